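"""ITS2 excision from rDNA amplicons via conserved 5.8S/28S flank motifs.

The ITS2 proper is delimited by the 3' end of the 5.8S gene and the 5' start
of the 28S gene.  Professional annotation uses profile HMMs trained on those
flanks; here the flanks are located by scanning position-weight profiles with
a mismatch budget, which behaves identically on the strongly conserved flank
regions this pipeline targets.  The default profiles below are plain-majority
approximations of the Viridiplantae 5.8S tail / 28S head consensus, not the
published HMMs, and can be overridden from config.

After excision the two flanks are hybridised in antiparallel to reconstruct
the B9 stem — the conserved duplex (8 bp in Chloropicophyceae) whose presence
validates that the cut points are the true processing boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .formats_io import RnaSequence, VALID_PAIRS

logger = logging.getLogger(__name__)

#: Approximate Viridiplantae 5.8S 3'-tail consensus (last 30 nt; the final
#: eight form the 5' arm of the B9 stem).  Approximation, not the HMM used by
#: the ITS2 database.
VIRIDIPLANTAE_58S_TAIL = "GAACGCAGCGAAAUGCGAUACG" + "GGUACCGC"

#: Approximate Viridiplantae 28S 5'-head consensus (first 30 nt; the first
#: eight form the 3' arm of the B9 stem).
VIRIDIPLANTAE_28S_HEAD = "GCGGUACC" + "AACCCGCUGAACUUAAGCAUAU"

DEFAULT_MOTIF_LEN = 14


class BoundaryNotFound(ValueError):
    """No flank motif hit above threshold on the named side."""


@dataclass(frozen=True)
class MotifProfile:
    """A position-weight profile over ACGU; scanned with a mismatch budget."""

    weights: tuple  # per position: dict base -> weight in [0, 1]

    @classmethod
    def from_consensus(cls, consensus: str) -> "MotifProfile":
        consensus = consensus.upper().replace("T", "U")
        return cls(tuple({b: (1.0 if b == c else 0.0) for b in "ACGU"} for c in consensus))

    def __len__(self) -> int:
        return len(self.weights)

    def score(self, window: str) -> float:
        return sum(w.get(b, 0.0) for w, b in zip(self.weights, window))

    def mismatches(self, window: str) -> int:
        return sum(1 for w, b in zip(self.weights, window) if w.get(b, 0.0) < 0.5)


@dataclass(frozen=True)
class FlankModel:
    """Flank motifs and search settings for boundary location."""

    motif_5p: MotifProfile = field(
        default_factory=lambda: MotifProfile.from_consensus(
            VIRIDIPLANTAE_58S_TAIL[-DEFAULT_MOTIF_LEN:]
        )
    )
    motif_3p: MotifProfile = field(
        default_factory=lambda: MotifProfile.from_consensus(
            VIRIDIPLANTAE_28S_HEAD[:DEFAULT_MOTIF_LEN]
        )
    )
    max_mismatch: int = 3
    search_window: int = 60

    def __post_init__(self) -> None:
        if len(self.motif_5p) == 0 or len(self.motif_3p) == 0:
            raise ValueError("flank motifs must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class B9Helix:
    """The reconstructed 5.8S/28S hybridisation stem."""

    stem_pairs: tuple  # ((offset from 5.8S 3' end, offset from 28S 5' start, 'WC'|'wobble'), ...)
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.stem_pairs):
            raise ValueError("B9 length must equal number of stem pairs")


def _scan(seq: str, motif: MotifProfile, lo: int, hi: int, max_mismatch: int) -> list[tuple[float, int]]:
    """All (score, start) hits of *motif* in seq[lo:hi] within the mismatch budget."""
    m = len(motif)
    hits = []
    for start in range(lo, min(hi, len(seq) - m) + 1):
        window = seq[start : start + m]
        if len(window) < m:
            break
        if motif.mismatches(window) <= max_mismatch:
            hits.append((motif.score(window), start))
    return hits


def build_b9(flank5: str, flank3: str, max_arm: int = 16) -> B9Helix:
    """Longest contiguous antiparallel duplex between the 5.8S 3' end and 28S 5' start.

    Offsets count inward from the ITS2: offset ``k`` on the 5.8S side is the
    residue ``k`` positions before the ITS2 start; on the 28S side, ``k``
    positions after the ITS2 end.  Pair types distinguish Watson-Crick from
    GU wobble.  If no duplex of at least 2 bp exists a zero-length helix is
    returned with a warning.
    """
    if len(flank5) < 8 or len(flank3) < 8:
        raise ValueError("both flanks must be at least 8 nt for B9 reconstruction")
    u = flank5[-max_arm:][::-1]  # u[k] = residue k before ITS2 start
    v = flank3[:max_arm]  # v[k] = residue k after ITS2 end
    best: list[tuple[int, int]] = []
    # a run pairs (u[a], v[b]) and extends with (a+1, b+1) moving away from
    # the ITS2 on the 5.8S side requires moving away on the 28S side too:
    # pairs (u[a+t], v[b+t]) are antiparallel-stacked
    for a0 in range(len(u)):
        for b0 in range(len(v)):
            if a0 > 0 and b0 > 0:
                continue  # runs are scanned from their inner end
            run: list[tuple[int, int]] = []
            a, b = a0, b0
            while a < len(u) and b < len(v):
                if (u[a], v[b]) in VALID_PAIRS:
                    run.append((a, b))
                    if len(run) > len(best):
                        best = list(run)
                else:
                    run = []
                a += 1
                b += 1
    if len(best) < 2:
        warnings.warn("no B9 duplex of >= 2 bp found between flanks")
        return B9Helix(stem_pairs=(), length=0)
    pairs = tuple(
        (a, b, "WC" if frozenset((u[a], v[b])) in ({frozenset("AU"), frozenset("GC")}) else "wobble")
        for a, b in best
    )
    return B9Helix(stem_pairs=pairs, length=len(pairs))


def locate_flanks(
    amplicon: RnaSequence, model: FlankModel | None = None
) -> tuple[int, int, str, str]:
    """Locate the ITS2 inside an amplicon.

    Returns ``(its2_start, its2_end, flank5, flank3)`` with 0-based half-open
    ITS2 coordinates; ``flank5``/``flank3`` are the residues outside them.
    Among equal-scoring motif hits, the combination maximising the resulting
    B9 stem is preferred, then the 5'-most.
    """
    model = model or FlankModel()
    seq = amplicon.residues
    m5, m3 = len(model.motif_5p), len(model.motif_3p)
    if len(seq) <= m5 + m3:
        raise BoundaryNotFound(
            f"{amplicon.id!r}: amplicon ({len(seq)} nt) shorter than both flank motifs"
        )
    hits5 = _scan(seq, model.motif_5p, 0, model.search_window - m5, model.max_mismatch)
    if not hits5:
        raise BoundaryNotFound(f"{amplicon.id!r}: 5' boundary not found")
    hits3 = _scan(
        seq, model.motif_3p, max(0, len(seq) - model.search_window), len(seq) - m3,
        model.max_mismatch,
    )
    if not hits3:
        raise BoundaryNotFound(f"{amplicon.id!r}: 3' boundary not found")

    top5 = max(s for s, _ in hits5)
    top3 = max(s for s, _ in hits3)
    cand5 = [p for s, p in hits5 if s == top5]
    cand3 = [p for s, p in hits3 if s == top3]
    best = None
    for p5 in cand5:
        for p3 in cand3:
            start = p5 + m5
            end = p3
            if end <= start:
                continue
            b9 = build_b9(seq[:start], seq[end:]) if start >= 8 and len(seq) - end >= 8 else None
            b9len = b9.length if b9 else 0
            key = (b9len, -start, -end)
            if best is None or key > best[0]:
                best = (key, start, end)
    if best is None:
        raise BoundaryNotFound(f"{amplicon.id!r}: flank hits overlap; no ITS2 interval")
    _, start, end = best
    return start, end, seq[:start], seq[end:]


def extract_its2(
    amplicon: RnaSequence,
    model: FlankModel | None = None,
    assume_its2: bool = False,
) -> tuple[RnaSequence, B9Helix | None]:
    """Excise the ITS2 and report the reconstructed B9 stem.

    With ``assume_its2`` the input is passed through unchanged (pre-excised
    sequences) and no B9 stem is reported.
    """
    if assume_its2:
        return amplicon, None
    start, end, flank5, flank3 = locate_flanks(amplicon, model)
    b9 = build_b9(flank5, flank3)
    its2 = RnaSequence(
        id=amplicon.id,
        residues=amplicon.residues[start:end],
        clade_label=amplicon.clade_label,
        source=amplicon.source,
    )
    return its2, b9
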