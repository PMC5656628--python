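"""Compensatory base change (CBC) classification and the pairwise CBC/hCBC matrix.

A CBC is a change at a paired position where *both* nucleotides differ
between two structures while pairing is retained; a hemi-CBC (hCBC) changes
only one side (Watson-Crick <-> wobble toggles included); a change that
destroys pairing (N-N <-> N x N) is a non-CBC.  Counting is phenetic: every
pair of taxa (or clade consensus sequences) is compared directly at each
conserved base-pair position of the alignment, without reconstructing
ancestral states.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .formats_io import CONCRETE, GAP, StructuredAlignment, VALID_PAIRS
from .hallmarks import annotate_helices

logger = logging.getLogger(__name__)

IDENTICAL = "identical"
CBC = "CBC"
HCBC = "hCBC"
NONCBC = "nonCBC"
NOT_COMPARABLE = "notComparable"

#: helices whose conserved pairs enter the matrix (helix IV is excluded)
COUNTED_HELICES = ("I", "II", "III")


def classify_change(a: tuple[str, str], b: tuple[str, str]) -> str:
    """Classify the change between base pairs *a* and *b*.

    Symmetric and defined on all ordered base combinations: ambiguity codes
    or gaps make the comparison ``notComparable``; two valid pairs differing
    on both sides are a CBC, on one side an hCBC; if pairing is present on
    one side of the comparison only (or on neither, with a sequence change),
    the change is a non-CBC.
    """
    a = (a[0].upper(), a[1].upper())
    b = (b[0].upper(), b[1].upper())
    bases = (*a, *b)
    if any(x not in CONCRETE for x in bases):
        return NOT_COMPARABLE
    if a == b:
        return IDENTICAL
    a_valid = a in VALID_PAIRS
    b_valid = b in VALID_PAIRS
    if a_valid and b_valid:
        changed = (a[0] != b[0]) + (a[1] != b[1])
        return CBC if changed == 2 else HCBC
    return NONCBC


@dataclass(frozen=True)
class ConsensusPair:
    """One conserved base-pair position of the alignment."""

    bp_id: int  # 1-based ID in 5'->3' order of the 5' column
    col5: int  # 0-based alignment columns
    col3: int
    helix: str
    support: float  # fraction of rows paired here


@dataclass(frozen=True)
class PairChange:
    bp_id: int
    columns: tuple[int, int]
    from_pair: tuple[str, str]
    to_pair: tuple[str, str]
    category: str
    helix: str


def _row_column_pairs(aln: StructuredAlignment) -> list[dict]:
    """Per row: map of (col5, col3) alignment-column pairs plus helix labels."""
    out = []
    for row in aln.rows:
        structure = row.degap()
        ann = annotate_helices(structure)
        labels = ann.pair_labels()
        # degapped position -> column
        pos2col = [c for c, ch in enumerate(row.residues) if ch != GAP]
        pairs = {}
        for i, j in structure.pairs():
            pairs[(pos2col[i], pos2col[j])] = labels.get((i, j))
        out.append(pairs)
    return out


def _conserved_columns(
    aln: StructuredAlignment, threshold: float, grouping: dict | None
) -> np.ndarray:
    """Boolean mask of columns that are base-conserved at *threshold*.

    With a taxon->group mapping, conservation is assessed within each group
    (the convention of lineage-level consensus structures: a position fixed
    within every lineage is conserved even when lineages differ from one
    another, which is exactly what a diagnostic CBC position looks like).
    Without grouping the criterion is global.
    """
    n_cols = aln.n_cols
    if grouping:
        groups: dict[str, list[int]] = {}
        for idx, rid in enumerate(aln.ids):
            groups.setdefault(grouping[rid], []).append(idx)
        member_sets = list(groups.values())
    else:
        member_sets = [list(range(len(aln.rows)))]
    ok = np.ones(n_cols, dtype=bool)
    for c in range(n_cols):
        col = aln.residue_column(c)
        for members in member_sets:
            chars = [col[i] for i in members if col[i] != GAP]
            if not chars:
                ok[c] = False
                break
            vals, counts = np.unique(chars, return_counts=True)
            if counts.max() / len(chars) < threshold:
                ok[c] = False
                break
    return ok


def consensus_pairs(
    aln: StructuredAlignment,
    min_frac: float = 0.9,
    conservation: float = 0.7,
    grouping: dict | None = None,
    helices: tuple = COUNTED_HELICES,
) -> list[ConsensusPair]:
    """Conserved base-pair positions of the alignment, numbered 5'->3'.

    A column pair qualifies when it is paired identically in at least
    ``min_frac`` of rows, both columns pass the base-conservation filter,
    and its majority helix label is one of *helices* (I, II, III by default
    — the lateral IIIa and helix IV are excluded, as are unconserved apical
    regions via the conservation filter).  Crossing pairs are resolved by
    support, then 5'-most.  An empty result is allowed (with a warning).
    """
    row_pairs = _row_column_pairs(aln)
    n_rows = len(row_pairs)
    counts: dict[tuple[int, int], int] = {}
    label_votes: dict[tuple[int, int], dict] = {}
    for pairs in row_pairs:
        for cp, label in pairs.items():
            counts[cp] = counts.get(cp, 0) + 1
            if label is not None:
                votes = label_votes.setdefault(cp, {})
                votes[label] = votes.get(label, 0) + 1

    conserved = _conserved_columns(aln, conservation, grouping)
    cands = []
    for (c5, c3), cnt in counts.items():
        support = cnt / n_rows
        if support < min_frac:
            continue
        if not (conserved[c5] and conserved[c3]):
            continue
        votes = label_votes.get((c5, c3), {})
        if not votes:
            continue
        helix = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        if helix not in helices:
            continue
        cands.append((c5, c3, helix, support))

    # enforce consistent nesting: greedy by support (desc), then 5'-most
    cands.sort(key=lambda t: (-t[3], t[0]))
    accepted: list[tuple[int, int, str, float]] = []
    for c5, c3, helix, support in cands:
        ok = True
        for a5, a3, _h, _s in accepted:
            crossing = (a5 < c5 < a3 < c3) or (c5 < a5 < c3 < a3)
            shared = len({a5, a3} & {c5, c3}) > 0
            if crossing or shared:
                ok = False
                break
        if ok:
            accepted.append((c5, c3, helix, support))
    accepted.sort(key=lambda t: t[0])
    if not accepted:
        warnings.warn("no consensus base pairs passed the filters")
    return [
        ConsensusPair(bp_id=k + 1, col5=c5, col3=c3, helix=h, support=s)
        for k, (c5, c3, h, s) in enumerate(accepted)
    ]


@dataclass
class CbcMatrix:
    """Symmetric pairwise CBC/hCBC counts with per-cell position lists."""

    taxa: list
    cbc: np.ndarray
    hcbc: np.ndarray
    positions: dict  # (taxon_a, taxon_b) sorted -> {"CBC": [bp_id...], "hCBC": [...]}

    def __post_init__(self) -> None:
        for m in (self.cbc, self.hcbc):
            if not np.array_equal(m, m.T) or np.any(np.diag(m) != 0):
                raise ValueError("CBC matrices must be symmetric with zero diagonal")
        for (a, b), lists in self.positions.items():
            i, j = self.taxa.index(a), self.taxa.index(b)
            if len(lists["CBC"]) != self.cbc[i, j] or len(lists["hCBC"]) != self.hcbc[i, j]:
                raise ValueError("position lists inconsistent with counts")

    def get(self, a: str, b: str, kind: str = CBC) -> int:
        m = self.cbc if kind == CBC else self.hcbc
        return int(m[self.taxa.index(a), self.taxa.index(b)])

    def positions_of(self, a: str, b: str, kind: str = CBC) -> list[int]:
        key = tuple(sorted((a, b)))
        if key not in self.positions:
            return []
        return list(self.positions[key][kind])


def _consensus_row(aln: StructuredAlignment, members: list[str]) -> str:
    """Majority symbol per column over the member rows (gap counts as a symbol)."""
    rows = [aln.row(m).residues for m in members]
    out = []
    for c in range(aln.n_cols):
        col = [r[c] for r in rows]
        vals, counts = np.unique(col, return_counts=True)
        best = max(zip(counts, vals), key=lambda t: (t[0], t[1] != GAP))
        out.append(best[1])
    return "".join(out)


def cbc_matrix(
    aln: StructuredAlignment,
    pairs: list[ConsensusPair],
    grouping: dict | None = None,
) -> CbcMatrix:
    """Pairwise CBC/hCBC matrix over taxa or clade consensus sequences.

    With *grouping* (taxon -> clade), each clade is collapsed to a majority
    consensus sequence and the matrix is clade x clade; otherwise it is
    strain x strain.  Positions with a gap or ambiguity on either side are
    not comparable and are excluded from the counts (logged at debug level).
    """
    if grouping is not None:
        missing = [t for t in aln.ids if t not in grouping]
        if missing:
            raise ValueError(f"taxa absent from grouping: {missing}")
        clades: dict[str, list[str]] = {}
        for rid in aln.ids:
            clades.setdefault(grouping[rid], []).append(rid)
        units = list(clades)
        seqs = {u: _consensus_row(aln, members) for u, members in clades.items()}
    else:
        units = list(aln.ids)
        seqs = {u: aln.row(u).residues for u in units}
    if len(units) < 2:
        raise ValueError("cbc_matrix needs at least 2 comparison units")

    n = len(units)
    cbc = np.zeros((n, n), dtype=int)
    hcbc = np.zeros((n, n), dtype=int)
    positions: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = units[i], units[j]
            lists = {CBC: [], HCBC: []}
            for cp in pairs:
                pa = (seqs[a][cp.col5], seqs[a][cp.col3])
                pb = (seqs[b][cp.col5], seqs[b][cp.col3])
                cat = classify_change(pa, pb)
                if cat == NOT_COMPARABLE:
                    logger.debug("bp %d not comparable between %s and %s", cp.bp_id, a, b)
                elif cat in (CBC, HCBC):
                    lists[cat].append(cp.bp_id)
            cbc[i, j] = cbc[j, i] = len(lists[CBC])
            hcbc[i, j] = hcbc[j, i] = len(lists[HCBC])
            positions[tuple(sorted((a, b)))] = {"CBC": lists[CBC], "hCBC": lists[HCBC]}
    return CbcMatrix(units, cbc, hcbc, positions)


def lineage_diagnostic_cbcs(
    aln: StructuredAlignment,
    pairs: list[ConsensusPair],
    group_a: list[str],
    group_b: list[str],
) -> list[int]:
    """bp_ids at which *every* member of A differs from *every* member of B by a CBC."""
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    rows = {rid: aln.row(rid).residues for rid in list(group_a) + list(group_b)}
    out = []
    for cp in pairs:
        diagnostic = True
        for a in group_a:
            for b in group_b:
                pa = (rows[a][cp.col5], rows[a][cp.col3])
                pb = (rows[b][cp.col5], rows[b][cp.col3])
                if classify_change(pa, pb) != CBC:
                    diagnostic = False
                    break
            if not diagnostic:
                break
        if diagnostic:
            out.append(cp.bp_id)
    return out
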