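"""Nested secondary-structure prediction by weighted base-pair maximisation.

The folder maximises a weighted count of base pairs (GC=3, AU=2, GU=1) over
all pseudoknot-free structures, subject to a minimum hairpin-loop length and,
by default, a no-lonely-pairs rule: every helix run must contain at least two
directly stacked pairs.  This is a deliberately simple, exactly testable
substitute for a thermodynamic folder — downstream, structures are chosen
among near-optimal candidates by ITS2 hallmark content rather than by energy,
so the scoring model only needs to put the biologically annotated topology
within the candidate set.

A brute-force enumerator over all valid pair sets (guarded to short
sequences) serves as the independent oracle in the test suite.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats_io import UNPAIRED, RnaSequence, SecondaryStructure, parse_dotbracket

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# integer encoding: A C G U -> 0..3, anything else (ambiguity) -> 4 (unpairable)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

#: default pair weights, indexed [base_i, base_j]; 0 = not allowed
def _default_score_table() -> np.ndarray:
    t = np.zeros((5, 5), dtype=np.int64)
    t[2, 1] = t[1, 2] = 3  # GC
    t[0, 3] = t[3, 0] = 2  # AU
    t[2, 3] = t[3, 2] = 1  # GU
    return t


_SCORES = _default_score_table()
NEG = -(10**9)


@dataclass(frozen=True)
class FoldParams:
    """Scoring and search parameters for the folder.

    ``pair_scores`` maps ``"GC"``/``"AU"``/``"GU"`` (order-insensitive) to
    positive integer weights. ``subopt_delta`` is in the same score units.
    """

    pair_scores: dict = field(default_factory=lambda: {"GC": 3, "AU": 2, "GU": 1})
    min_loop: int = 3
    subopt_delta: int = 2
    max_candidates: int = 20
    forbid_lonely_pairs: bool = True

    def __post_init__(self) -> None:
        for k, v in self.pair_scores.items():
            if v <= 0:
                raise ValueError(f"pair score for {k} must be positive, got {v}")
        if self.min_loop < 1:
            raise ValueError("min_loop must be >= 1")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")

    def score_table(self) -> np.ndarray:
        t = np.zeros((5, 5), dtype=np.int64)
        for key, w in self.pair_scores.items():
            a, b = _BASE_INDEX[key[0]], _BASE_INDEX[key[1]]
            t[a, b] = t[b, a] = w
        return t


@dataclass(frozen=True)
class FoldCandidate:
    structure: SecondaryStructure
    score: int
    rank: int


def encode_sequence(seq: RnaSequence) -> np.ndarray:
    """Map residues to 0..3 (ACGU) or 4 (ambiguity; never paired)."""
    return np.array([_BASE_INDEX.get(c, 4) for c in seq.residues], dtype=np.int64)


# ---------------------------------------------------------------------------
# DP fill
# ---------------------------------------------------------------------------
#
# W[i, j]   best score on [i, j]
# H[i, j]   best score on [i, j] given that (i, j) is the outermost pair of a
#           stacked run of >= L_min pairs going inward
#
# W(i,j) = max( W(i+1,j),  max_k  H(i,k) + W(k+1,j) )
#
# H(i,j) = max over run length L >= L_min of
#             sum_{t<L} s(i+t, j-t)  +  W(i+L, j-L)
#          with every pair in the run allowed and the innermost pair
#          respecting the hairpin minimum.
#
# With L_min = 1 this is plain Nussinov (maximum weighted pairs); with
# L_min = 2 every helix run has at least two stacked pairs.


@njit(cache=True)
def _fill(enc, table, min_loop, l_min):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    W = np.zeros((n + 1, n + 1), dtype=np.int64)
    H = np.full((n + 1, n + 1), NEG, dtype=np.int64)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # H(i, j)
            best_h = NEG
            run = 0
            L = 0
            while True:
                a = i + L
                b = j - L
                if a >= b:
                    break
                s = table[enc[a], enc[b]]
                if s == 0:
                    break
                if b - a - 1 < min_loop:
                    break
                run += s
                L += 1
                if L >= l_min:
                    inner = 0
                    if j - L >= i + L:
                        inner = W[i + L, j - L]
                    tot = run + inner
                    if tot > best_h:
                        best_h = tot
            H[i, j] = best_h
            # W(i, j)
            best = W[i + 1, j] if i + 1 <= j else 0
            for k in range(i + min_loop + 1, j + 1):
                hk = H[i, k]
                if hk == NEG:
                    continue
                rest = W[k + 1, j] if k + 1 <= j else 0
                tot = hk + rest
                if tot > best:
                    best = tot
            W[i, j] = best
    return W, H


def _fill_matrices(enc: np.ndarray, params: FoldParams) -> tuple[np.ndarray, np.ndarray]:
    table = params.score_table()
    l_min = 2 if params.forbid_lonely_pairs else 1
    return _fill(enc, table, np.int64(params.min_loop), np.int64(l_min))


def _traceback(enc: np.ndarray, W: np.ndarray, H: np.ndarray, params: FoldParams) -> np.ndarray:
    """Deterministic traceback: among co-optimal choices at (i, j), pairing i
    with the smallest admissible partner wins over leaving i unpaired."""
    table = params.score_table()
    l_min = 2 if params.forbid_lonely_pairs else 1
    n = enc.shape[0]
    partner = np.full(n, UNPAIRED, dtype=np.int64)
    agenda = [(0, n - 1)]
    while agenda:
        i, j = agenda.pop()
        if i >= j:
            continue
        target = W[i, j]
        done = False
        for k in range(i + params.min_loop + 1, j + 1):
            if H[i, k] == NEG:
                continue
            rest = W[k + 1, j] if k + 1 <= j else 0
            if H[i, k] + rest == target:
                L = _run_length(enc, table, W, i, k, params.min_loop, l_min, int(H[i, k]))
                for t in range(L):
                    partner[i + t], partner[k - t] = k - t, i + t
                agenda.append((i + L, k - L))
                agenda.append((k + 1, j))
                done = True
                break
        if not done:
            agenda.append((i + 1, j))
    return partner


def _run_length(
    enc: np.ndarray,
    table: np.ndarray,
    W: np.ndarray,
    i: int,
    k: int,
    min_loop: int,
    l_min: int,
    h_target: int,
) -> int:
    """Smallest stacked-run length L >= l_min realising H(i, k) = h_target."""
    run = 0
    L = 0
    while True:
        a, b = i + L, k - L
        if a >= b:
            break
        s = int(table[enc[a], enc[b]])
        if s == 0 or b - a - 1 < min_loop:
            break
        run += s
        L += 1
        if L >= l_min:
            inner = int(W[i + L, k - L]) if k - L > i + L else 0
            if run + inner == h_target:
                return L
    raise AssertionError("traceback failed to reproduce H value")  # pragma: no cover


def fold_optimal(seq: RnaSequence, params: FoldParams | None = None) -> FoldCandidate:
    """Best-scoring nested structure under the weighted-pair model.

    Sequences too short to form any hairpin return an all-unpaired structure
    with a warning rather than an error.
    """
    params = params or FoldParams()
    n = len(seq)
    if n < params.min_loop + 2:
        warnings.warn(f"{seq.id!r}: too short to fold ({n} nt); returning unpaired structure")
        return FoldCandidate(SecondaryStructure.all_unpaired(seq), 0, 0)
    enc = encode_sequence(seq)
    W, H = _fill_matrices(enc, params)
    partner = _traceback(enc, W, H, params)
    structure = SecondaryStructure(seq, partner, min_loop=params.min_loop)
    return FoldCandidate(structure, int(W[0, n - 1]), 0)


# ---------------------------------------------------------------------------
# Suboptimal enumeration (Wuchty-style over the W/H recursions)
# ---------------------------------------------------------------------------


def enumerate_suboptimal(seq: RnaSequence, params: FoldParams | None = None) -> list[FoldCandidate]:
    """All distinct structures within ``subopt_delta`` of the optimum.

    Returned sorted by score descending, then lexicographic dot-bracket, and
    truncated to ``max_candidates``.  Enumeration work is internally capped so
    pathological sequences cannot blow up; the optimum itself is always
    included.
    """
    params = params or FoldParams()
    n = len(seq)
    if n < params.min_loop + 2:
        return [fold_optimal(seq, params)]
    enc = encode_sequence(seq)
    table = params.score_table()
    l_min = 2 if params.forbid_lonely_pairs else 1
    W, H = _fill_matrices(enc, params)
    opt = int(W[0, n - 1])
    floor = opt - params.subopt_delta

    results: list[tuple[int, tuple[tuple[int, int], ...]]] = []
    cap = max(50 * params.max_candidates, 500)

    def bound(new_got, new_pending):
        tot = new_got
        for a, b in new_pending:
            if a < b:
                tot += int(W[a, b])
        return tot

    # best-first over partial structures: a partial is (pending intervals,
    # pairs so far, pair score so far); its bound (score + DP optimum of all
    # pending intervals) is admissible, so complete structures pop from the
    # heap in non-increasing score order and the cap cannot starve
    # near-optimal structures in favour of deep low-score variants.
    import heapq

    counter = 0
    heap = [(-bound(0, [(0, n - 1)]), 0, [(0, n - 1)], (), 0)]
    popped_complete = 0
    while heap and popped_complete < cap:
        neg_bnd, _, pending, pairs, got = heapq.heappop(heap)
        if -neg_bnd < floor:
            break
        # skip exhausted (single-residue/empty) intervals
        while pending and pending[-1][0] >= pending[-1][1]:
            pending = pending[:-1]
        if not pending:
            results.append((got, pairs))
            popped_complete += 1
            continue
        (i, j), rest = pending[-1], pending[:-1]
        # choice 1: i unpaired
        cand_pending = list(rest) + [(i + 1, j)]
        b1 = bound(got, cand_pending)
        if b1 >= floor:
            counter += 1
            heapq.heappush(heap, (-b1, counter, cand_pending, pairs, got))
        # choice 2: pair i with k via a stacked run of length L
        for k in range(i + params.min_loop + 1, j + 1):
            if H[i, k] == NEG:
                continue
            run = 0
            L = 0
            while True:
                a, b = i + L, k - L
                if a >= b:
                    break
                s = int(table[enc[a], enc[b]])
                if s == 0 or b - a - 1 < params.min_loop:
                    break
                run += s
                L += 1
                if L >= l_min:
                    new_pairs = pairs + tuple((i + t, k - t) for t in range(L))
                    cand_pending = list(rest) + [(k + 1, j), (i + L, k - L)]
                    b2 = bound(got + run, cand_pending)
                    if b2 >= floor:
                        counter += 1
                        heapq.heappush(heap, (-b2, counter, cand_pending, new_pairs, got + run))
    # dedupe and rank; the DP optimum is always included even if the
    # enumeration cap truncated the search
    best = fold_optimal(seq, params)
    seen: dict[str, tuple[int, str, tuple]] = {
        best.structure.dotbracket: (
            best.score,
            best.structure.dotbracket,
            tuple(int(x) for x in best.structure.partner),
        )
    }
    for score, pairs in results:
        if score < floor:
            continue
        partner = np.full(n, UNPAIRED, dtype=np.int64)
        for a, b in pairs:
            partner[a], partner[b] = b, a
        db = "".join("." if p == UNPAIRED else ("(" if x < p else ")") for x, p in enumerate(partner))
        if db not in seen or seen[db][0] < score:
            seen[db] = (score, db, tuple(partner))
    ranked = sorted(seen.values(), key=lambda t: (-t[0], t[1]))[: params.max_candidates]
    out = []
    for rank, (score, _db, partner) in enumerate(ranked):
        out.append(
            FoldCandidate(
                SecondaryStructure(seq, np.array(partner), min_loop=params.min_loop),
                int(score),
                rank,
            )
        )
    if not out:  # enumeration cap pathologies: fall back to the optimum
        out = [fold_optimal(seq, params)]
    return out


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

BRUTE_FORCE_MAX_LEN = 16


def brute_force_fold(
    seq: RnaSequence, params: FoldParams | None = None
) -> tuple[int, list[SecondaryStructure]]:
    """Exhaustive enumeration of every valid nested pair set (testing oracle).

    Guarded to sequences of at most :data:`BRUTE_FORCE_MAX_LEN` nt.  Returns
    the optimal score and all optimal structures.
    """
    params = params or FoldParams()
    n = len(seq)
    if n > BRUTE_FORCE_MAX_LEN:
        raise ValueError(f"brute_force_fold limited to {BRUTE_FORCE_MAX_LEN} nt, got {n}")
    enc = encode_sequence(seq)
    table = params.score_table()
    l_min = 2 if params.forbid_lonely_pairs else 1

    def lonely_ok(pairset: frozenset) -> bool:
        if l_min == 1:
            return True
        for (a, b) in pairset:
            if (a + 1, b - 1) not in pairset and (a - 1, b + 1) not in pairset:
                return False
        return True

    all_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + params.min_loop + 1, n)
        if table[enc[i], enc[j]] > 0
    ]

    results: dict[int, list[tuple]] = {}

    def rec(idx: int, chosen: list, used: set):
        fs = frozenset(chosen)
        if lonely_ok(fs):
            score = sum(int(table[enc[a], enc[b]]) for a, b in chosen)
            results.setdefault(score, []).append(tuple(sorted(chosen)))
        for t in range(idx, len(all_pairs)):
            i, j = all_pairs[t]
            if i in used or j in used:
                continue
            # nestedness vs chosen
            ok = True
            for (a, b) in chosen:
                if a < i < b < j or i < a < j < b:
                    ok = False
                    break
            if not ok:
                continue
            chosen.append((i, j))
            used.add(i)
            used.add(j)
            rec(t + 1, chosen, used)
            chosen.pop()
            used.discard(i)
            used.discard(j)

    rec(0, [], set())
    best_score = max(results) if results else 0
    structures = []
    for pairs in sorted(set(results.get(best_score, [()]))):
        partner = np.full(n, UNPAIRED, dtype=np.int64)
        for a, b in pairs:
            partner[a], partner[b] = b, a
        structures.append(SecondaryStructure(seq, partner, min_loop=params.min_loop))
    return best_score, structures


# ---------------------------------------------------------------------------
# Optional external thermodynamic engine
# ---------------------------------------------------------------------------


def fold_external(seq: RnaSequence, program: str = "RNAfold") -> SecondaryStructure:
    """Hook to an external thermodynamic folder (e.g. ``RNAfold``).

    Purely optional alternative engine: parses the dot-bracket from the
    program's stdout.  Never required by the pipeline.
    """
    proc = subprocess.run(
        [program, "--noPS"], input=f">{seq.id}\n{seq.residues}\n", text=True,
        capture_output=True, check=True,
    )
    for line in proc.stdout.splitlines():
        token = line.split()[0] if line.split() else ""
        if token and set(token) <= set(".()"):
            return parse_dotbracket(token, seq)
    raise RuntimeError(f"{program} produced no dot-bracket for {seq.id!r}")
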