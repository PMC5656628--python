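"""p-distances (complete deletion), group distances, conservation profiles, NJ trees.

The distance conventions mirror the common MEGA settings for ITS work:
*complete deletion* removes every alignment column containing a gap or an
ambiguity code in any row before counting mismatches, so all pairwise
distances are computed over the same site set; the between-group distance is
the unweighted mean over all cross-group pairs (the maximum is also exposed,
since "divergence as high as X%" statements refer to it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import CONCRETE, GAP, StructuredAlignment

#: IUPAC code for each set of observed concrete bases
_IUPAC_OF = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("GC"): "S", frozenset("AU"): "W",
    frozenset("GU"): "K", frozenset("AC"): "M", frozenset("CGU"): "B", frozenset("AGU"): "D",
    frozenset("ACU"): "H", frozenset("ACG"): "V", frozenset("ACGU"): "N",
}


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray  # symmetric, fractions in [0, 1]
    n_sites_used: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def _rows_to_matrix(rows: list[str]) -> np.ndarray:
    return np.array([list(r) for r in rows], dtype="U1")


def p_distance_matrix(aln: StructuredAlignment | list, pairwise_deletion: bool = False) -> DistanceMatrix:
    """Uncorrected p-distances between all rows.

    Default is complete deletion: any column with a gap or ambiguity in any
    row is removed once, globally, and every distance is a fraction of the
    retained sites.  ``pairwise_deletion`` restricts removal to each pair
    (the published numbers this pipeline emulates assume complete deletion).
    """
    if isinstance(aln, StructuredAlignment):
        ids = aln.ids
        rows = [r.residues for r in aln.rows]
    else:
        ids = [r[0] for r in aln]
        rows = [r[1] for r in aln]
    if len(rows) < 2:
        raise ValueError("p-distance needs at least 2 rows")
    M = _rows_to_matrix(rows)
    concrete = np.isin(M, list(CONCRETE))
    n = len(rows)
    if not pairwise_deletion:
        keep = concrete.all(axis=0)
        n_used = int(keep.sum())
        if n_used == 0:
            raise ValueError("complete deletion removed every column")
        Mk = M[:, keep]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.mean(Mk[i] != Mk[j])
        return DistanceMatrix(ids, d, n_used)
    d = np.zeros((n, n))
    min_used = M.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            keep = concrete[i] & concrete[j]
            used = int(keep.sum())
            if used == 0:
                raise ValueError(f"no comparable sites between rows {ids[i]!r} and {ids[j]!r}")
            min_used = min(min_used, used)
            d[i, j] = d[j, i] = np.mean(M[i, keep] != M[j, keep])
    return DistanceMatrix(ids, d, min_used)


def between_group_distance(dm: DistanceMatrix, g1, g2, stat: str = "mean") -> float:
    """Mean (or max) pairwise distance across two disjoint taxon groups."""
    g1, g2 = list(g1), list(g2)
    if not g1 or not g2:
        raise ValueError("groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError(f"groups overlap: {sorted(set(g1) & set(g2))}")
    idx1 = [dm.taxa.index(t) for t in g1]
    idx2 = [dm.taxa.index(t) for t in g2]
    vals = dm.d[np.ix_(idx1, idx2)].ravel()
    if stat == "mean":
        return float(vals.mean())
    if stat == "max":
        return float(vals.max())
    raise ValueError(f"unknown stat {stat!r}")


def within_group_distance(dm: DistanceMatrix, group, stat: str = "mean") -> float:
    """Mean (or max) pairwise distance inside one group (0 for singletons)."""
    idx = [dm.taxa.index(t) for t in group]
    if len(idx) < 2:
        return 0.0
    vals = [dm.d[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]]
    return float(np.max(vals) if stat == "max" else np.mean(vals))


@dataclass
class ConservationProfile:
    consensus: str  # per column: concrete base if conserved, else IUPAC cover
    max_fraction: np.ndarray
    threshold: float


def conservation_profile(aln: StructuredAlignment, threshold: float = 0.7) -> ConservationProfile:
    """Majority-rule consensus with IUPAC fallback below the threshold.

    Fractions are taken among non-gap symbols per column; columns whose top
    base falls below the threshold get the IUPAC code covering every
    concrete base observed there (ambiguity codes in rows contribute to the
    cover as N).
    """
    cons = []
    fracs = np.zeros(aln.n_cols)
    for c in range(aln.n_cols):
        col = [ch for ch in aln.residue_column(c) if ch != GAP]
        if not col:
            cons.append(GAP)
            continue
        bases, counts = np.unique(col, return_counts=True)
        top = int(np.argmax(counts))
        frac = counts[top] / len(col)
        fracs[c] = frac
        if frac >= threshold and bases[top] in CONCRETE:
            cons.append(str(bases[top]))
        else:
            observed = frozenset(b for b in col if b in CONCRETE) or frozenset("ACGU")
            key = observed if observed in _IUPAC_OF else frozenset("ACGU")
            cons.append(_IUPAC_OF[key])
    return ConservationProfile("".join(cons), fracs, threshold)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> str:
    """Standard neighbor joining; returns an unrooted Newick string.

    Ties in the Q-criterion are broken on the lowest taxon-index pair, so the
    topology is deterministic.  Negative branch lengths (possible on
    non-additive input) are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = [_quote(t) for t in dm.taxa]
    D = dm.d.astype(float).copy()
    active = list(range(n))
    newick = {i: labels[i] for i in active}

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # new node u replaces i
        u = i
        newick[u] = f"({newick[i]}:{li:.6g},{newick[j]}:{lj:.6g})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[u, k] = D[k, u] = max(duk, 0.0)
        active.remove(j)

    i, j = active
    return f"({newick[i]}:{max(D[i, j], 0.0):.6g},{newick[j]}:0);"


def _quote(taxon: str) -> str:
    if any(ch in taxon for ch in " ():,;"):
        return "'" + taxon.replace("'", "_") + "'"
    return taxon
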