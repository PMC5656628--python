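"""Helix annotation and ITS2 hallmark scoring.

ITS2 secondary structures across eukaryotes share a small set of diagnostic
features ("hallmarks"): a four-helix core with helix III the longest, a
pyrimidine-pyrimidine mismatch in helix II, a YRRY motif on the 5' side of
helix III, and fixed-length spacers between helices I-II and II-III.  Because
a purely score-based folder returns several near-optimal candidates, the
hallmarks are what pick the biologically meaningful structure: candidates are
annotated, scored for hallmark content, and the best-scoring one is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .folding import FoldCandidate
from .formats_io import UNPAIRED, RnaSequence, SecondaryStructure

PYRIMIDINES = frozenset("CU")
PURINES = frozenset("AG")

#: default expected spacer lengths (nt) between consecutive helices; only the
#: (I,II) and (II,III) spacers are length-conserved in the Chlorophyta
#: consensus, so only those are scored.
DEFAULT_EXPECTED_SPACERS = {("I", "II"): 4, ("II", "III"): 5}

#: internal loops up to this many unpaired nt per side stay within one helix
DEFAULT_BULGE_TOL = 2


@dataclass(frozen=True)
class HelixSegment:
    """A maximal stack of pairs (internal loops <= bulge_tol per side)."""

    pairs: tuple[tuple[int, int], ...]  # (i, j) outer -> inner
    label: str | None = None

    @property
    def outer(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner(self) -> tuple[int, int]:
        return self.pairs[-1]

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def arm5(self) -> tuple[int, int]:
        """0-based inclusive range of the 5' arm."""
        return (self.outer[0], self.inner[0])

    @property
    def arm3(self) -> tuple[int, int]:
        return (self.inner[1], self.outer[1])

    def relabel(self, label: str) -> "HelixSegment":
        return HelixSegment(self.pairs, label)


@dataclass
class HelixAnnotation:
    """Labeled helices of an ITS2 structure plus inter-helix spacer lengths.

    ``helices`` holds the labelled root-level segments I..IV in 5'->3' order
    (missing labels simply absent); ``segments`` holds every segment with its
    label (including IIIa and unlabelled minor stems); ``spacers`` maps
    consecutive-region keys to unpaired spacer lengths.
    """

    helices: list[HelixSegment]
    segments: list[HelixSegment]
    spacers: dict[tuple[str, str], int]
    missing: list[str] = field(default_factory=list)

    def get(self, label: str) -> HelixSegment | None:
        for seg in self.segments:
            if seg.label == label:
                return seg
        return None

    def pair_labels(self) -> dict[tuple[int, int], str]:
        """Map every labelled base pair (i, j) to its helix label."""
        out: dict[tuple[int, int], str] = {}
        for seg in self.segments:
            if seg.label is None:
                continue
            for p in seg.pairs:
                out[p] = seg.label
        return out


@dataclass
class HallmarkReport:
    """Outcome of the hallmark checks on one annotated structure."""

    yy_mismatch: dict
    yrry: dict
    spacer_ok: dict
    first_two_bp: dict
    helix_iv_agg: bool
    agg_score: float

    def summary(self) -> str:
        yy = self.yy_mismatch
        yr = self.yrry
        return (
            f"Y-Y={'x'.join(yy['bases']) if yy['found'] else '-'} "
            f"YRRY={yr['motif'] if yr['found'] else '-'} "
            f"score={self.agg_score:g}"
        )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def find_segments(s: SecondaryStructure, bulge_tol: int = DEFAULT_BULGE_TOL) -> list[HelixSegment]:
    """Split the structure's pairs into helix segments.

    Consecutive pairs remain in one segment when separated by at most
    ``bulge_tol`` unpaired nt on each side (bulges and small internal loops
    such as the helix-II Y-Y mismatch do not break a helix).
    """
    pairs = sorted(s.pairs())
    segments: list[HelixSegment] = []
    cur: list[tuple[int, int]] = []
    for p in pairs:
        if cur:
            pi, pj = cur[-1]
            if p[0] - pi - 1 <= bulge_tol and pj - p[1] - 1 <= bulge_tol and p[0] > pi and p[1] < pj:
                cur.append(p)
                continue
            segments.append(HelixSegment(tuple(cur)))
            cur = []
        cur.append(p)
    if cur:
        segments.append(HelixSegment(tuple(cur)))
    return segments


def _encloses(outer: HelixSegment, inner: HelixSegment) -> bool:
    (a, b) = outer.outer
    (c, d) = inner.outer
    return a < c and d < b


def annotate_helices(
    s: SecondaryStructure,
    bulge_tol: int = DEFAULT_BULGE_TOL,
) -> HelixAnnotation:
    """Label the four root-level helices I..IV and a lateral IIIa branch.

    Root-level segments (not enclosed by any other segment) are candidates;
    the four longest are labelled I-IV in 5'->3' order.  If helix III's
    multiloop contains more than one child segment, the shortest child is the
    lateral helix IIIa and the remaining children keep label III (the distal
    continuation of the helix).  Fewer than four root segments is not an
    error: the annotation simply flags the missing labels.
    """
    segments = find_segments(s, bulge_tol)
    n = len(s)
    roots = [seg for seg in segments if not any(_encloses(o, seg) for o in segments if o is not seg)]
    roots.sort(key=lambda seg: seg.outer[0])

    ordered_labels = ["I", "II", "III", "IV"]
    if len(roots) >= 4:
        chosen = sorted(roots, key=lambda seg: (-seg.length, seg.outer[0]))[:4]
        chosen = sorted(chosen, key=lambda seg: seg.outer[0])
        missing = []
    else:
        chosen = roots
        missing = ordered_labels[len(roots):]

    label_of: dict[int, str] = {}
    for lab, seg in zip(ordered_labels, chosen):
        label_of[id(seg)] = lab

    labelled: list[HelixSegment] = []
    helices: list[HelixSegment] = []
    used = set()
    for seg in segments:
        lab = label_of.get(id(seg))
        if lab:
            seg2 = seg.relabel(lab)
            labelled.append(seg2)
            helices.append(seg2)
            used.add(id(seg))

    # descend into helix III: label its children (IIIa = shortest of >=2)
    h3 = next((seg for seg in labelled if seg.label == "III"), None)
    if h3 is not None:
        children = [
            seg
            for seg in segments
            if id(seg) not in used
            and h3.inner[0] < seg.outer[0]
            and seg.outer[1] < h3.inner[1]
            and not any(
                _encloses(o, seg)
                for o in segments
                if o is not seg and id(o) not in used and h3.inner[0] < o.outer[0] and o.outer[1] < h3.inner[1]
            )
        ]
        children.sort(key=lambda seg: seg.outer[0])
        if len(children) >= 2:
            iiia = min(children, key=lambda seg: (seg.length, seg.outer[0]))
            for seg in children:
                lab = "IIIa" if seg is iiia else "III"
                labelled.append(seg.relabel(lab))
                used.add(id(seg))
        elif len(children) == 1:
            labelled.append(children[0].relabel("III"))
            used.add(id(children[0]))
    for seg in segments:
        if id(seg) not in used:
            labelled.append(seg)

    labelled.sort(key=lambda seg: seg.outer[0])

    # spacers between consecutive labelled root helices (and sequence ends,
    # which in a bare ITS2 abut the B9 stem)
    spacers: dict[tuple[str, str], int] = {}
    order = [seg for seg in helices]
    order.sort(key=lambda seg: seg.outer[0])
    prev_label, prev_end = "B9", -1
    for seg in order:
        spacers[(prev_label, seg.label)] = seg.outer[0] - prev_end - 1
        prev_label, prev_end = seg.label, seg.outer[1]
    spacers[(prev_label, "B9")] = n - prev_end - 1

    return HelixAnnotation(helices=order, segments=labelled, spacers=spacers, missing=missing)


# ---------------------------------------------------------------------------
# hallmark checks
# ---------------------------------------------------------------------------


def _internal_loops(seg_pairs) -> list[tuple[list[int], list[int]]]:
    """Internal loops (unpaired runs per side) between consecutive pairs of one segment."""
    loops = []
    for (i1, j1), (i2, j2) in zip(seg_pairs, seg_pairs[1:]):
        side5 = list(range(i1 + 1, i2))
        side3 = list(range(j2 + 1, j1))
        if side5 or side3:
            loops.append((side5, side3))
    return loops


def check_hallmarks(
    ann: HelixAnnotation,
    seq: RnaSequence,
    expected_spacers: dict | None = None,
    weights: dict | None = None,
) -> HallmarkReport:
    """Score an annotated structure against the ITS2 hallmarks.

    Absent features score zero; nothing raises.  ``agg_score`` =
    4 x (all four helices present) + 2 x (Y-Y mismatch in helix II)
    + 2 x (YRRY on the 5' arm of helix III) + 1 per spacer of expected
    length.  The AGG motif at the base of helix IV is recorded but never
    scored.
    """
    expected_spacers = DEFAULT_EXPECTED_SPACERS if expected_spacers is None else expected_spacers
    w = {"four_helices": 4.0, "yy": 2.0, "yrry": 2.0, "spacer": 1.0}
    if weights:
        w.update(weights)
    res = seq.residues

    yy = {"found": False, "bases": (), "position": None}
    h2 = ann.get("II")
    if h2 is not None:
        for side5, side3 in _internal_loops(h2.pairs):
            if len(side5) == 1 and len(side3) == 1:
                b5, b3 = res[side5[0]], res[side3[0]]
                if b5 in PYRIMIDINES and b3 in PYRIMIDINES:
                    yy = {"found": True, "bases": (b5, b3), "position": side5[0] + 1}
                    break

    yrry = {"found": False, "motif": None, "position": None}
    h3 = ann.get("III")
    if h3 is not None:
        # scan the full 5' side of helix III (basal arm through the distal
        # continuation), bulged residues included
        arm_positions = sorted(
            {p for seg in ann.segments if seg.label == "III" for p in range(seg.arm5[0], seg.arm5[1] + 1)}
        )
        arm = "".join(res[p] for p in arm_positions)
        for off in range(len(arm) - 3):
            window = arm[off : off + 4]
            if (
                window[0] in PYRIMIDINES
                and window[1] in PURINES
                and window[2] in PURINES
                and window[3] in PYRIMIDINES
            ):
                yrry = {
                    "found": True,
                    "motif": window,
                    "position": arm_positions[off] + 1,
                }
                break

    spacer_ok = {}
    for key, exp_len in expected_spacers.items():
        got = ann.spacers.get(tuple(key))
        spacer_ok[tuple(key)] = got == exp_len

    first_two = {}
    for lab in ("I", "II", "III"):
        seg = ann.get(lab)
        if seg is not None:
            first_two[lab] = [
                (res[i], res[j]) for (i, j) in seg.pairs[:2]
            ]

    # AGG at the base of helix IV: recorded only
    h4 = ann.get("IV")
    agg = False
    if h4 is not None:
        start = h4.outer[0]
        agg = res[max(0, start - 3) : start] == "AGG" or res[start : start + 3] == "AGG"

    four = all(ann.get(lab) is not None for lab in ("I", "II", "III", "IV"))
    score = (
        w["four_helices"] * four
        + w["yy"] * yy["found"]
        + w["yrry"] * yrry["found"]
        + w["spacer"] * sum(bool(v) for v in spacer_ok.values())
    )
    return HallmarkReport(
        yy_mismatch=yy,
        yrry=yrry,
        spacer_ok=spacer_ok,
        first_two_bp=first_two,
        helix_iv_agg=agg,
        agg_score=score,
    )


def select_structure(
    candidates: list[FoldCandidate],
    seq: RnaSequence,
    expected_spacers: dict | None = None,
    bulge_tol: int = DEFAULT_BULGE_TOL,
) -> tuple[SecondaryStructure, HallmarkReport]:
    """Pick the candidate maximising (hallmark score, fold score, -rank)."""
    if not candidates:
        raise ValueError("select_structure requires at least one candidate")
    best = None
    for cand in candidates:
        ann = annotate_helices(cand.structure, bulge_tol=bulge_tol)
        rep = check_hallmarks(ann, seq, expected_spacers=expected_spacers)
        key = (rep.agg_score, cand.score, -cand.rank)
        if best is None or key > best[0]:
            best = (key, cand.structure, rep)
    return best[1], best[2]


def select_structures_dataset(
    seqs: list[RnaSequence],
    fold_params=None,
    expected_spacers: dict | None = None,
    bulge_tol: int = DEFAULT_BULGE_TOL,
) -> dict[str, tuple[SecondaryStructure, "HallmarkReport"]]:
    """Hallmark- and homology-guided structure assignment for a whole dataset.

    Each sequence is folded to its score-optimal structure and scored for
    hallmarks.  Among the sequences whose optimum shows the fullest hallmark
    content, a reference is chosen by how well its structure transfers onto
    every other sequence (total retained pairs and hallmark content of the
    transferred structures); the reference structure is then mapped onto all
    sequences by homology transfer.  A sequence falls back to its own optimal
    fold only where the transferred structure loses hallmark content.

    This mirrors how ITS2 structures are assigned in practice: one confident
    fold anchors the dataset and the rest follow by comparison across
    strains, which suppresses the idiosyncratic rearrangements that point
    mutations induce in single-sequence folding.
    """
    from .folding import fold_optimal
    from .struct_align import transfer_structure

    folded = []
    for seq in seqs:
        cand = fold_optimal(seq, fold_params)
        ann = annotate_helices(cand.structure, bulge_tol=bulge_tol)
        rep = check_hallmarks(ann, seq, expected_spacers=expected_spacers)
        folded.append((seq, cand, rep))

    best_agg = max(t[2].agg_score for t in folded)
    ref_candidates = [t for t in folded if t[2].agg_score == best_agg]

    def ref_quality(r):
        tot_pairs = 0
        tot_agg = 0.0
        for seq, _cand, _rep in folded:
            ts = transfer_structure((r[0], r[1].structure), seq)
            tot_pairs += ts.n_pairs()
            tot_agg += check_hallmarks(
                annotate_helices(ts, bulge_tol=bulge_tol), seq, expected_spacers=expected_spacers
            ).agg_score
        return (tot_agg, tot_pairs, r[0].id)

    ref_seq, ref_cand, _ = max(ref_candidates, key=ref_quality)

    out: dict[str, tuple[SecondaryStructure, HallmarkReport]] = {}
    for seq, cand, own_rep in folded:
        transferred = transfer_structure((ref_seq, ref_cand.structure), seq)
        tr_rep = check_hallmarks(
            annotate_helices(transferred, bulge_tol=bulge_tol), seq, expected_spacers=expected_spacers
        )
        # the transferred structure wins unless it loses hallmark content:
        # cross-strain consistency beats a higher single-sequence pair score
        if tr_rep.agg_score >= own_rep.agg_score:
            out[seq.id] = (transferred, tr_rep)
        else:
            out[seq.id] = (cand.structure, own_rep)
    return out
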