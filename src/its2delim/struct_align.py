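"""Sequence+structure alignment in a 12-letter alphabet, 4SALE style.

Each residue is encoded as a (base, pairing-state) symbol — state unpaired,
helix-opening or helix-closing — and alignments are computed over that
product alphabet so that a base match inside a helix outranks the same match
across different structural contexts.  A progressive profile-profile scheme
over a neighbor-joining guide tree produces the multiple alignment; pairwise
alignment uses affine gaps (Gotoh) with a deterministic traceback.

Also provides structure homology transfer: mapping a reference structure's
base pairs onto a homologous sequence through a pairwise alignment, which is
how structures are propagated from a well-folding reference strain to the
rest of a dataset (the automated counterpart of curating structures by
comparison across strains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix, nj_tree
from .formats_io import (
    GAP,
    UNPAIRED,
    AlignedRow,
    RnaSequence,
    SecondaryStructure,
    StructuredAlignment,
    VALID_PAIRS,
)

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

# ---------------------------------------------------------------------------
# 12-letter encoding
# ---------------------------------------------------------------------------

_BASES = "ACGU"
_STATE_OF_CHAR = {".": 0, "(": 1, ")": 2}
#: display alphabet: unpaired ACGU, helix-opening acgu, helix-closing WXYZ
_SYMBOLS = {("A", 0): "A", ("C", 0): "C", ("G", 0): "G", ("U", 0): "U",
            ("A", 1): "a", ("C", 1): "c", ("G", 1): "g", ("U", 1): "u",
            ("A", 2): "W", ("C", 2): "X", ("G", 2): "Y", ("U", 2): "Z"}
_DECODE = {v: k for k, v in _SYMBOLS.items()}
_STATE_CHAR = {0: ".", 1: "(", 2: ")"}

#: integer encoding for the aligner: state*5 + base, base 4 = ambiguity
_AMBIG = 4
N_CODES = 15


def encode(seq: RnaSequence, structure: SecondaryStructure) -> str:
    """Encode (sequence, structure) as a string over the 12-letter alphabet.

    IUPAC ambiguity codes are only legal at unpaired positions and are passed
    through verbatim (they decode back to themselves)."""
    if len(seq) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    db = structure.dotbracket
    out = []
    for ch, st in zip(seq.residues, db):
        if ch in _BASES:
            out.append(_SYMBOLS[(ch, _STATE_OF_CHAR[st])])
        else:
            if st != ".":
                raise ValueError(f"ambiguity code {ch!r} at a paired position")
            out.append(ch)
    return "".join(out)


def decode(encoded: str, id: str = "decoded") -> tuple[RnaSequence, str]:
    """Inverse of :func:`encode`; returns the sequence and dot-bracket."""
    bases, states = [], []
    for ch in encoded:
        if ch in _DECODE:
            b, s = _DECODE[ch]
            bases.append(b)
            states.append(_STATE_CHAR[s])
        else:
            bases.append(ch)
            states.append(".")
    return RnaSequence(id=id, residues="".join(bases)), "".join(states)


def _to_ints(seq: RnaSequence, structure: SecondaryStructure) -> np.ndarray:
    db = structure.dotbracket
    out = np.empty(len(seq), dtype=np.int64)
    for i, (ch, st) in enumerate(zip(seq.residues, db)):
        b = _BASES.index(ch) if ch in _BASES else _AMBIG
        out[i] = _STATE_OF_CHAR[st] * 5 + b
    return out


@dataclass(frozen=True)
class AlignScoring:
    """Substitution/gap parameters for sequence+structure alignment."""

    match: float = 2.0
    mismatch: float = -1.0
    structure_state_mismatch_penalty: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def matrix(self) -> np.ndarray:
        """(15, 15) substitution matrix over state*5+base codes."""
        S = np.empty((N_CODES, N_CODES))
        for x in range(N_CODES):
            for y in range(N_CODES):
                bx, by = x % 5, y % 5
                sx, sy = x // 5, y // 5
                s = self.match if (bx == by and bx != _AMBIG) else self.mismatch
                if sx != sy:
                    s += self.structure_state_mismatch_penalty
                S[x, y] = s
        return S


SEQUENCE_ONLY = AlignScoring(structure_state_mismatch_penalty=0.0)


# ---------------------------------------------------------------------------
# pairwise Gotoh on a precomputed column-score matrix
# ---------------------------------------------------------------------------

_NEG = -1e30


@njit(cache=True)
def _gotoh(sub, gap_open, gap_extend):  # pragma: no cover - numba kernel
    """Global affine-gap DP over a (n, m) column-score matrix.

    Returns (score, traceback ops) where ops are 0=diag, 1=up (gap in the
    second input), 2=left.  Tie preference: diagonal, then up, then left.
    """
    n, m = sub.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in y (vertical, consumes x)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in x (horizontal, consumes y)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    # traceback
    ops = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    state = 0
    final = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] == final:
        state = 0
    elif X[n, m] == final:
        state = 1
    else:
        state = 2
    while i > 0 or j > 0:
        if i == 0:
            ops[k] = 2; j -= 1; k += 1; continue
        if j == 0:
            ops[k] = 1; i -= 1; k += 1; continue
        if state == 0:
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if M[i - 1, j - 1] == prev:
                nstate = 0
            elif X[i - 1, j - 1] == prev:
                nstate = 1
            else:
                nstate = 2
            ops[k] = 0; i -= 1; j -= 1; k += 1; state = nstate
        elif state == 1:
            if M[i - 1, j] + gap_open == X[i, j]:
                nstate = 0
            elif X[i - 1, j] + gap_extend == X[i, j]:
                nstate = 1
            else:
                nstate = 2
            ops[k] = 1; i -= 1; k += 1; state = nstate
        else:
            if M[i, j - 1] + gap_open == Y[i, j]:
                nstate = 0
            elif Y[i, j - 1] + gap_extend == Y[i, j]:
                nstate = 2
            else:
                nstate = 1
            ops[k] = 2; j -= 1; k += 1; state = nstate
    return final, ops[:k][::-1].copy()


def _pairwise_ops(x: np.ndarray, y: np.ndarray, S: np.ndarray, scoring: AlignScoring):
    sub = S[np.ix_(x, y)]
    return _gotoh(sub, scoring.gap_open, scoring.gap_extend)


def align_pair(
    x: tuple[RnaSequence, SecondaryStructure],
    y: tuple[RnaSequence, SecondaryStructure],
    scoring: AlignScoring | None = None,
) -> tuple[StructuredAlignment, float]:
    """Optimal global pairwise alignment of two encoded sequences."""
    scoring = scoring or AlignScoring()
    sx, stx = x
    sy, sty = y
    if len(sx) == 0 or len(sy) == 0:
        raise ValueError("align_pair requires non-empty inputs")
    S = scoring.matrix()
    score, ops = _pairwise_ops(_to_ints(sx, stx), _to_ints(sy, sty), S, scoring)
    rows = _ops_to_rows(ops, [(sx, stx)], [(sy, sty)])
    return StructuredAlignment(rows), float(score)


def _ops_to_rows(ops, group_x, group_y):
    """Expand traceback ops into gapped rows for two groups of records."""
    def expand(records, take_flags):
        rows = []
        for seq, struct in records:
            db = struct.dotbracket
            res_out, st_out = [], []
            pos = 0
            for take in take_flags:
                if take:
                    res_out.append(seq.residues[pos])
                    st_out.append(db[pos])
                    pos += 1
                else:
                    res_out.append(GAP)
                    st_out.append(GAP)
            rows.append(AlignedRow(seq.id, "".join(res_out), "".join(st_out)))
        return rows

    take_x = [op in (0, 1) for op in ops]
    take_y = [op in (0, 2) for op in ops]
    return expand(group_x, take_x) + expand(group_y, take_y)


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------


def _profile(rows: list[AlignedRow]) -> np.ndarray:
    """(n_cols, 16) frequency profile: 15 residue codes + gap (index 15)."""
    n_cols = len(rows[0].residues)
    P = np.zeros((n_cols, N_CODES + 1))
    for row in rows:
        for c, (rch, sch) in enumerate(zip(row.residues, row.states)):
            if rch == GAP:
                P[c, N_CODES] += 1
            else:
                b = _BASES.index(rch) if rch in _BASES else _AMBIG
                P[c, _STATE_OF_CHAR[sch] * 5 + b] += 1
    return P / len(rows)


def _merge(rows_x: list[AlignedRow], rows_y: list[AlignedRow], S16: np.ndarray, scoring: AlignScoring) -> list[AlignedRow]:
    Px, Py = _profile(rows_x), _profile(rows_y)
    sub = Px @ S16 @ Py.T
    _, ops = _gotoh(sub, scoring.gap_open, scoring.gap_extend)

    def expand(rows, take_flags):
        out = []
        for row in rows:
            res_out, st_out = [], []
            pos = 0
            for take in take_flags:
                if take:
                    res_out.append(row.residues[pos])
                    st_out.append(row.states[pos])
                    pos += 1
                else:
                    res_out.append(GAP)
                    st_out.append(GAP)
            out.append(AlignedRow(row.id, "".join(res_out), "".join(st_out)))
        return out

    take_x = [op in (0, 1) for op in ops]
    take_y = [op in (0, 2) for op in ops]
    return expand(rows_x, take_x) + expand(rows_y, take_y)


def _guide_distances(records, scoring: AlignScoring) -> DistanceMatrix:
    """p-distances from pairwise sequence-only alignments (guide-tree input)."""
    S = SEQUENCE_ONLY.matrix()
    n = len(records)
    d = np.zeros((n, n))
    ints = [_to_ints(s, st) for s, st in records]
    for i in range(n):
        for j in range(i + 1, n):
            _, ops = _pairwise_ops(ints[i], ints[j], S, SEQUENCE_ONLY)
            xi = records[i][0].residues
            yj = records[j][0].residues
            pi = pj = diff = comp = 0
            for op in ops:
                if op == 0:
                    comp += 1
                    diff += xi[pi] != yj[pj]
                    pi += 1
                    pj += 1
                elif op == 1:
                    pi += 1
                else:
                    pj += 1
            d[i, j] = d[j, i] = diff / comp if comp else 1.0
    return DistanceMatrix([s.id for s, _ in records], d, comp)


def progressive_msa(
    records: list[tuple[RnaSequence, SecondaryStructure]],
    scoring: AlignScoring | None = None,
    guide_tree: str | None = None,
) -> StructuredAlignment:
    """Progressive profile-profile MSA over a guide tree.

    The guide tree defaults to neighbor joining on p-distances from pairwise
    sequence-only alignments; a user Newick can be supplied instead (its leaf
    labels must match the record ids).  Row order in the result equals input
    order.
    """
    scoring = scoring or AlignScoring()
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least 2 records")
    ids = [s.id for s, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")

    if len(records) == 2:
        aln, _ = align_pair(records[0], records[1], scoring)
        merged = aln.rows
    else:
        if guide_tree is None:
            guide_tree = nj_tree(_guide_distances(records, scoring))
        order = _merge_order(guide_tree, ids)
        S = scoring.matrix()
        S16 = np.zeros((N_CODES + 1, N_CODES + 1))
        S16[:N_CODES, :N_CODES] = S
        groups: dict[int, list[AlignedRow]] = {}
        for i, (seq, struct) in enumerate(records):
            groups[i] = [AlignedRow(seq.id, seq.residues, struct.dotbracket)]
        next_id = len(records)
        for left, right in order:
            groups[next_id] = _merge(groups.pop(left), groups.pop(right), S16, scoring)
            next_id += 1
        (merged,) = [rows for rows in groups.values()]

    by_id = {row.id: row for row in merged}
    return StructuredAlignment([by_id[i] for i in ids])


def _merge_order(newick: str, ids: list[str]) -> list[tuple[int, int]]:
    """Postorder pair-merge schedule from a Newick guide tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = leaf_names - set(ids)
    if unknown:
        raise ValueError(f"guide tree contains unknown leaf ids: {sorted(unknown)}")
    missing = set(ids) - leaf_names
    if missing:
        raise ValueError(f"guide tree is missing leaf ids: {sorted(missing)}")

    index = {name: i for i, name in enumerate(ids)}
    next_id = [len(ids)]
    order: list[tuple[int, int]] = []

    def visit(node) -> int:
        if node.is_leaf():
            return index[node.taxon.label]
        child_ids = [visit(ch) for ch in node.child_nodes()]
        cur = child_ids[0]
        for other in child_ids[1:]:
            order.append((cur, other))
            cur = next_id[0]
            next_id[0] += 1
        return cur

    visit(tree.seed_node)
    return order


# ---------------------------------------------------------------------------
# structure homology transfer
# ---------------------------------------------------------------------------


def transfer_structure(
    reference: tuple[RnaSequence, SecondaryStructure],
    target: RnaSequence,
    scoring: AlignScoring | None = None,
    min_loop: int = 3,
) -> SecondaryStructure:
    """Map a reference structure's pairs onto a homologous target sequence.

    The target is aligned to the reference (sequence scoring); every
    reference pair whose two columns map to target residues that can legally
    pair is transferred.  Pairs violating the hairpin minimum after indels
    and pairs left without a stacked neighbour are dropped, so the result is
    a valid, lonely-pair-free structure.
    """
    scoring = scoring or SEQUENCE_ONLY
    ref_seq, ref_struct = reference
    S = scoring.matrix()
    tgt_struct = SecondaryStructure.all_unpaired(target)
    _, ops = _pairwise_ops(_to_ints(ref_seq, ref_struct), _to_ints(target, tgt_struct), S, scoring)
    # map reference position -> target position (None at gaps)
    ref2tgt: dict[int, int] = {}
    pi = pj = 0
    for op in ops:
        if op == 0:
            ref2tgt[pi] = pj
            pi += 1
            pj += 1
        elif op == 1:
            pi += 1
        else:
            pj += 1
    partner = np.full(len(target), UNPAIRED, dtype=np.int64)
    pairs = []
    for i, j in ref_struct.pairs():
        ti, tj = ref2tgt.get(i), ref2tgt.get(j)
        if ti is None or tj is None:
            continue
        if tj - ti - 1 < min_loop:
            continue
        if (target.residues[ti], target.residues[tj]) in VALID_PAIRS:
            pairs.append((ti, tj))
    kept = set(pairs)
    # prune lonely pairs (no directly stacked neighbour)
    changed = True
    while changed:
        changed = False
        for (a, b) in sorted(kept):
            if (a + 1, b - 1) not in kept and (a - 1, b + 1) not in kept:
                kept.discard((a, b))
                changed = True
    for a, b in kept:
        partner[a], partner[b] = b, a
    return SecondaryStructure(target, partner, min_loop=min_loop)
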