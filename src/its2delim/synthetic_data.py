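"""Clade-structured synthetic ITS2 datasets with a planted-change ledger.

The generator builds a Chlorophyta-style ITS2 consensus template — four
helices, a U x U mismatch in helix II, a UGGU box leading the 5' arm of
helix III, a lateral IIIa branch, fixed-length I-II and II-III spacers, and
5.8S/28S flanks that hybridise into an 8 bp B9 stem — then derives a
hierarchy of lineages, clades and strains from it by planting known changes:

* lineage- or clade-level CBCs and hCBCs at named stem positions,
* neutral wobble toggles in stems and free point mutations in loops,
* clade-level length variation in the apical regions (helix I/II tips, the
  IIIa loop), and
* a 7-9 nt spacer insertion carried by one lineage only, 3' of helix III.

Every applied change is recorded in a ledger; replaying the ledger on the
template reproduces each strain exactly, which is what makes every pipeline
stage testable against ground truth without downloading anything.

Stems are sampled from G/C pairs and unpaired regions are poly-A (plus the
hallmark nucleotides), which keeps the planted topology the unambiguous
optimum of the weighted-pair folding model.  This is a deliberate
idealisation; see the methods note for what it does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .formats_io import RnaSequence, SecondaryStructure, UNPAIRED, write_fasta
from .hallmarks import HelixAnnotation, annotate_helices
from .its2_extract import VIRIDIPLANTAE_28S_HEAD, VIRIDIPLANTAE_58S_TAIL

#: deterministic CBC partner for each valid pair (both sides change, pairing kept)
CBC_MAP = {
    ("G", "C"): ("A", "U"),
    ("C", "G"): ("U", "A"),
    ("A", "U"): ("G", "C"),
    ("U", "A"): ("C", "G"),
    ("G", "U"): ("C", "G"),
    ("U", "G"): ("G", "C"),
}

#: deterministic hCBC partner (one side changes, pairing kept)
HCBC_MAP = {
    ("G", "C"): ("G", "U"),
    ("C", "G"): ("U", "G"),
    ("A", "U"): ("G", "U"),
    ("U", "A"): ("U", "G"),
    ("G", "U"): ("G", "C"),
    ("U", "G"): ("C", "G"),
}


@dataclass(frozen=True)
class PlantedChange:
    """A change planted at a helix stem position for a whole lineage or clade."""

    helix: str  # 'I', 'II', 'III', 'IIIa', 'IV'
    stem_index: int  # index into the template helix's pair list, outer -> inner
    kind: str  # 'CBC' | 'hCBC'
    level: str  # 'lineage' | 'clade'
    target: tuple  # (lineage_idx,) or (lineage_idx, clade_idx)

    def __post_init__(self) -> None:
        if self.kind not in ("CBC", "hCBC"):
            raise ValueError(f"unknown planted change kind {self.kind!r}")
        if self.level not in ("lineage", "clade"):
            raise ValueError(f"unknown planted change level {self.level!r}")


def default_planted_cbcs() -> list[PlantedChange]:
    """Three lineage-level CBCs in helices II and III carried by lineage B.

    The helix III positions sit in the distal stem, 3' of the UGGU box —
    stem positions 0-4 are the basal stack and 5-8 carry the hallmark box
    itself, which planted changes must not disturb."""
    return [
        PlantedChange("II", 1, "CBC", "lineage", (1,)),
        PlantedChange("III", 9, "CBC", "lineage", (1,)),
        PlantedChange("III", 11, "CBC", "lineage", (1,)),
    ]


def default_planted_hcbcs() -> list[PlantedChange]:
    return [
        PlantedChange("I", 3, "hCBC", "clade", (0, 1)),
        PlantedChange("I", 5, "hCBC", "clade", (1, 0)),
    ]


@dataclass
class SimConfig:
    """Generator configuration.  Defaults are the study conditions the
    pipeline's acceptance checks run under: 2 lineages x 3 clades x 4 strains
    with three lineage-level CBCs planted in helices II/III."""

    seed: int = 1
    n_lineages: int = 2
    clades_per_lineage: int = 3
    strains_per_clade: int = 4
    planted_cbcs: list = field(default_factory=default_planted_cbcs)
    planted_hcbcs: list = field(default_factory=default_planted_hcbcs)
    loop_mut_rate: float = 0.02
    stem_neutral_rate: float = 0.02
    indel_regions: tuple = ("helixI_tip", "helixII_tip", "IIIa")
    indel_max_len: int = 2
    insertion_lineage: int = 1
    insertion_len_range: tuple = (7, 9)
    b9_stem_len: int = 8
    flank5_len: int = 30
    flank3_len: int = 30
    flank_mutations: int = 1
    # template geometry (pairs per helix; apical loop lengths)
    helix_arm_lengths: dict = field(
        default_factory=lambda: {"I": 9, "II_outer": 4, "II_inner": 5, "III_basal": 5,
                                 "III_distal": 7, "IIIa": 3, "IV": 6}
    )
    loop_lengths: dict = field(
        default_factory=lambda: {"I": 5, "II": 5, "III": 5, "IIIa": 4, "IV": 4}
    )
    spacer_lengths: dict = field(
        default_factory=lambda: {"sp0": 5, "sp1": 4, "sp2": 5, "sp3": 6, "tail": 4}
    )

    def __post_init__(self) -> None:
        for r in (self.loop_mut_rate, self.stem_neutral_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must be in [0, 1]")
        if any(v <= 0 for v in self.helix_arm_lengths.values()):
            raise ValueError("helix arm lengths must be positive")
        if not (2 <= self.b9_stem_len <= 8):
            raise ValueError("b9_stem_len must be between 2 and 8")
        lo, hi = self.insertion_len_range
        if lo > hi or lo < 0:
            raise ValueError("bad insertion length range")


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------


class _Site:
    """One residue of an evolving molecule; partners are object references so
    loop indels never invalidate pairing bookkeeping."""

    __slots__ = ("char", "partner", "region", "tpos")

    def __init__(self, char: str, region: str, tpos: int | None):
        self.char = char
        self.partner: "_Site | None" = None
        self.region = region
        self.tpos = tpos


class Template:
    """The consensus ITS2 as a list of sites plus named helix pair lists."""

    def __init__(self, sites: list[_Site], helix_pairs: dict, region_index: dict):
        self.sites = sites
        self.helix_pairs = helix_pairs  # label -> list of (site5, site3), outer->inner
        self.region_index = region_index  # region name -> list of site objects

    def sequence(self, id: str = "template") -> RnaSequence:
        return RnaSequence(id=id, residues="".join(s.char for s in self.sites))

    def structure(self, id: str = "template") -> SecondaryStructure:
        _, partner = _materialize(self.sites)
        return SecondaryStructure(self.sequence(id), partner)


def _sample_gc_arm(rng: np.random.Generator, n: int, avoid_yrry: bool = False) -> str:
    """Random G/C 5' arm; optionally resampled until free of any YRRY window.

    Over a G/C alphabet a YRRY window is exactly 'CGGC'; a 'CGG' suffix is
    also excluded because the arm 5' of the planted UGGU box would complete
    a YRRY window across the junction ('CGG' + 'U')."""
    while True:
        arm = "".join(rng.choice(["G", "C"], size=n))
        if not avoid_yrry or ("CGGC" not in arm and not arm.endswith("CGG")):
            return arm


_COMP = {"G": "C", "C": "G", "A": "U", "U": "A"}


def make_template(cfg: SimConfig) -> tuple[Template, RnaSequence, SecondaryStructure, HelixAnnotation]:
    """Build the consensus ITS2 (bare, without flanks).

    Returns the mutable :class:`Template` plus immutable sequence/structure/
    annotation views.  The template is deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 0])
    arms = cfg.helix_arm_lengths
    loops = cfg.loop_lengths
    sp = cfg.spacer_lengths

    sites: list[_Site] = []
    helix_pairs: dict[str, list] = {"I": [], "II": [], "III": [], "IIIa": [], "IV": []}
    region_index: dict[str, list] = {}

    def add(chars: str, region: str) -> list[_Site]:
        new = [_Site(c, region, None) for c in chars]
        sites.extend(new)
        region_index.setdefault(region, []).extend(new)
        return new

    def add_helix(label: str, arm5: str, loop_region: str, loop_len: int,
                  inner_builder=None, loop_chars: str | None = None):
        """Simple hairpin helix: arm5, loop (or nested content), arm3."""
        s5 = add(arm5, f"helix{label}_arm5")
        if inner_builder is not None:
            inner_builder()
        else:
            add(loop_chars or "A" * loop_len, loop_region)
        arm3 = "".join(_COMP[c] for c in reversed(arm5))
        s3 = add(arm3, f"helix{label}_arm3")
        for k in range(len(arm5)):
            a, b = s5[k], s3[len(arm5) - 1 - k]
            a.partner, b.partner = b, a
            helix_pairs[label].append((a, b))

    # spacer B9 -> I
    add("A" * sp["sp0"], "sp0")
    # helix I
    add_helix("I", _sample_gc_arm(rng, arms["I"]), "helixI_tip", loops["I"])
    # spacer I -> II (length-conserved hallmark)
    add("A" * sp["sp1"], "sp1")
    # helix II with the Y-Y (U x U) mismatch between outer and inner stacks
    outer5 = _sample_gc_arm(rng, arms["II_outer"])
    inner5 = _sample_gc_arm(rng, arms["II_inner"])
    o5 = add(outer5, "helixII_arm5")
    add("U", "helixII_yy5")
    i5 = add(inner5, "helixII_arm5")
    add("A" * loops["II"], "helixII_tip")
    i3 = add("".join(_COMP[c] for c in reversed(inner5)), "helixII_arm3")
    add("U", "helixII_yy3")
    o3 = add("".join(_COMP[c] for c in reversed(outer5)), "helixII_arm3")
    for k in range(len(outer5)):
        a, b = o5[k], o3[len(outer5) - 1 - k]
        a.partner, b.partner = b, a
        helix_pairs["II"].append((a, b))
    for k in range(len(inner5)):
        a, b = i5[k], i3[len(inner5) - 1 - k]
        a.partner, b.partner = b, a
        helix_pairs["II"].append((a, b))
    # spacer II -> III (length-conserved hallmark)
    add("A" * sp["sp2"], "sp2")
    # helix III: basal stack, multiloop with lateral IIIa then distal stack
    basal5 = _sample_gc_arm(rng, arms["III_basal"], avoid_yrry=True)
    b5 = add(basal5, "helixIII_arm5")

    def build_multiloop():
        add("AA", "helixIII_ml1")
        add_helix("IIIa", _sample_gc_arm(rng, arms["IIIa"]), "IIIa", loops["IIIa"])
        add("AA", "helixIII_ml2")
        distal5 = "UGGU" + _sample_gc_arm(rng, arms["III_distal"] - 4)
        add_helix("III_distal", distal5, "helixIII_tip", loops["III"])
        add("AA", "helixIII_ml3")

    helix_pairs["III_distal"] = []
    build_multiloop()
    b3 = add("".join(_COMP[c] for c in reversed(basal5)), "helixIII_arm3")
    for k in range(len(basal5)):
        a, b = b5[k], b3[len(basal5) - 1 - k]
        a.partner, b.partner = b, a
        helix_pairs["III"].append((a, b))
    # fold distal pairs into the helix III pair list (basal first, then distal)
    helix_pairs["III"].extend(helix_pairs.pop("III_distal"))
    # spacer III -> IV (lineage insertion lands here)
    add("A" * sp["sp3"], "sp3")
    # helix IV
    add_helix("IV", _sample_gc_arm(rng, arms["IV"]), "helixIV_tip", loops["IV"])
    # tail IV -> B9
    add("A" * sp["tail"], "tail")

    tpl = Template(sites, helix_pairs, region_index)
    for i, s in enumerate(sites):
        s.tpos = i
    seq = tpl.sequence()
    struct = tpl.structure()
    ann = annotate_helices(struct)
    return tpl, seq, struct, ann


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

LINEAGE_NAMES = "ABCDEFGH"


@dataclass
class StrainTruth:
    id: str
    lineage: int
    clade: int
    its2_seq: str
    its2_db: str
    its2_start: int  # in the amplicon, 0-based half-open
    its2_end: int
    amplicon_seq: str
    ops: list  # applied edit operations, in order


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset."""

    seed: int
    template_seq: str
    template_db: str
    strains: list  # of StrainTruth
    planted: dict  # resolved planted changes: kind -> list of dicts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "template_seq": self.template_seq,
            "template_db": self.template_db,
            "planted": self.planted,
            "strains": [asdict(s) for s in self.strains],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            template_seq=d["template_seq"],
            template_db=d["template_db"],
            strains=[StrainTruth(**s) for s in d["strains"]],
            planted=d["planted"],
        )


def clade_name(lineage: int, clade: int) -> str:
    return f"{LINEAGE_NAMES[lineage]}{clade + 1}"


def strain_id(lineage: int, clade: int, strain: int) -> str:
    return f"{clade_name(lineage, clade)}_s{strain + 1}"


def _materialize(sites: list[_Site]) -> tuple[str, np.ndarray]:
    index_of = {}
    for i, s in enumerate(sites):
        index_of[s] = i
    partner = np.full(len(sites), UNPAIRED, dtype=np.int64)
    for i, s in enumerate(sites):
        if s.partner is not None:
            partner[i] = index_of[s.partner]
    return "".join(s.char for s in sites), partner


def _copy_sites(sites: list[_Site]) -> list[_Site]:
    clones = [_Site(s.char, s.region, s.tpos) for s in sites]
    lookup = {id(s): c for s, c in zip(sites, clones)}
    for s, c in zip(sites, clones):
        if s.partner is not None:
            c.partner = lookup[id(s.partner)]
    return clones


def simulate(cfg: SimConfig) -> tuple[list[RnaSequence], SyntheticTruth]:
    """Generate amplicons (5.8S tail + ITS2 + 28S head) for every strain.

    Deterministic under a fixed seed; each strain draws from an RNG stream
    keyed by (seed, lineage, clade, strain) so adding strains never perturbs
    existing ones.
    """
    tpl, tseq, tstruct, _ann = make_template(cfg)

    # resolve planted changes against the template and check for conflicts
    occupied: dict[int, PlantedChange] = {}
    resolved: dict[str, list] = {"CBC": [], "hCBC": []}
    for change in list(cfg.planted_cbcs) + list(cfg.planted_hcbcs):
        pair_list = tpl.helix_pairs[change.helix]
        if not 0 <= change.stem_index < len(pair_list):
            raise ValueError(
                f"planted change references stem index {change.stem_index} "
                f"outside helix {change.helix} ({len(pair_list)} pairs)"
            )
        s5, s3 = pair_list[change.stem_index]
        if s5.tpos in occupied:
            raise ValueError(
                f"contradictory planted changes at helix {change.helix} "
                f"stem index {change.stem_index}"
            )
        occupied[s5.tpos] = change
        from_pair = (s5.char, s3.char)
        to_pair = (CBC_MAP if change.kind == "CBC" else HCBC_MAP)[from_pair]
        resolved[change.kind].append(
            {
                "helix": change.helix,
                "stem_index": change.stem_index,
                "level": change.level,
                "target": list(change.target),
                "tpos5": s5.tpos,
                "tpos3": s3.tpos,
                "from_pair": list(from_pair),
                "to_pair": list(to_pair),
            }
        )
    planted_positions = set(occupied)

    flank5 = VIRIDIPLANTAE_58S_TAIL[-cfg.flank5_len:]
    flank3 = VIRIDIPLANTAE_28S_HEAD[: cfg.flank3_len]
    if cfg.b9_stem_len < 8:
        # break B9 pairs beyond the configured stem length (outermost first)
        f5 = list(flank5)
        for off in range(cfg.b9_stem_len, 8):
            partner_base = flank3[off]
            f5[-1 - off] = "A" if partner_base in "GC" else "C"
        flank5 = "".join(f5)

    records: list[RnaSequence] = []
    strains: list[StrainTruth] = []
    base_seed = int(cfg.seed) % (2**31)

    for li in range(cfg.n_lineages):
        for ci in range(cfg.clades_per_lineage):
            clade_rng = np.random.default_rng([base_seed, 11, li, ci])
            # clade-level apical length variation
            indels = {}
            for reg in cfg.indel_regions:
                indels[reg] = int(
                    clade_rng.integers(-cfg.indel_max_len, cfg.indel_max_len + 1)
                )
            # the insertion is a lineage trait; its exact length (7-9 nt)
            # varies among clades of that lineage
            clade_ins_len = 0
            if li == cfg.insertion_lineage:
                clade_ins_len = int(
                    clade_rng.integers(cfg.insertion_len_range[0], cfg.insertion_len_range[1] + 1)
                )
            for si in range(cfg.strains_per_clade):
                rng = np.random.default_rng([base_seed, 22, li, ci, si])
                sites = _copy_sites(tpl.sites)
                by_tpos = {s.tpos: s for s in sites}
                ops: list = []

                # 1. planted lineage/clade changes
                for kind in ("CBC", "hCBC"):
                    for rc in resolved[kind]:
                        tgt = tuple(rc["target"])
                        hit = (rc["level"] == "lineage" and tgt == (li,)) or (
                            rc["level"] == "clade" and tgt == (li, ci)
                        )
                        if not hit:
                            continue
                        s5, s3 = by_tpos[rc["tpos5"]], by_tpos[rc["tpos3"]]
                        s5.char, s3.char = rc["to_pair"]
                        ops.append(
                            {
                                "op": "sub_pair",
                                "kind": kind,
                                "tpos5": rc["tpos5"],
                                "tpos3": rc["tpos3"],
                                "to": rc["to_pair"],
                            }
                        )

                # 2. strain-level neutral wobble toggles at unplanted stem pairs
                stem_pairs = [
                    (s, s.partner)
                    for s in sites
                    if s.partner is not None
                    and s.tpos is not None
                    and s.partner.tpos is not None
                    and s.tpos < s.partner.tpos
                    and s.tpos not in planted_positions
                ]
                for s5, s3 in stem_pairs:
                    if rng.random() < cfg.stem_neutral_rate:
                        pair = (s5.char, s3.char)
                        if pair in HCBC_MAP:
                            s5.char, s3.char = HCBC_MAP[pair]
                            ops.append(
                                {
                                    "op": "sub_pair",
                                    "kind": "wobble",
                                    "tpos5": s5.tpos,
                                    "tpos3": s3.tpos,
                                    "to": [s5.char, s3.char],
                                }
                            )

                # 3. strain-level free loop mutations
                for s in sites:
                    if s.partner is None and rng.random() < cfg.loop_mut_rate:
                        choices = [b for b in "ACGU" if b != s.char]
                        s.char = str(rng.choice(choices))
                        ops.append({"op": "sub", "tpos": s.tpos, "to": s.char})

                # 4. clade-level apical indels (loops only; loops never
                #    shrink below 3 nt so hairpins stay foldable)
                for region, delta in indels.items():
                    members = [s for s in sites if s.region == region]
                    if delta < 0:
                        removable = max(0, len(members) - 3)
                        take = min(-delta, removable)
                        for s in members[:take]:
                            sites.remove(s)
                        if take:
                            ops.append({"op": "del", "region": region, "n": take})
                    elif delta > 0:
                        anchor = sites.index(members[0])
                        for _ in range(delta):
                            sites.insert(anchor, _Site("A", region, None))
                        ops.append({"op": "ins", "region": region, "n": delta, "chars": "A" * delta})

                # 5. lineage-specific spacer insertion 3' of helix III
                if clade_ins_len:
                    anchor_site = tpl.region_index["sp3"][0]
                    pos = next(i for i, s in enumerate(sites) if s.tpos == anchor_site.tpos)
                    for _ in range(clade_ins_len):
                        sites.insert(pos, _Site("A", "lineage_insertion", None))
                    ops.append(
                        {"op": "ins", "region": "lineage_insertion", "n": clade_ins_len,
                         "chars": "A" * clade_ins_len}
                    )

                its2_seq, partner = _materialize(sites)
                db = "".join(
                    "." if p == UNPAIRED else ("(" if i < p else ")")
                    for i, p in enumerate(partner)
                )

                # flank mutations (outside the B9 octamer, outside motif core)
                f5, f3 = list(flank5), list(flank3)
                for _ in range(cfg.flank_mutations):
                    side = rng.integers(2)
                    if side == 0 and len(f5) > cfg.b9_stem_len + 2:
                        pos = int(rng.integers(0, len(f5) - cfg.b9_stem_len - 2))
                        f5[pos] = str(rng.choice([b for b in "ACGU" if b != f5[pos]]))
                        ops.append({"op": "flank_sub", "side": 5, "pos": pos, "to": f5[pos]})
                    elif side == 1 and len(f3) > cfg.b9_stem_len + 2:
                        pos = int(rng.integers(cfg.b9_stem_len + 2, len(f3)))
                        f3[pos] = str(rng.choice([b for b in "ACGU" if b != f3[pos]]))
                        ops.append({"op": "flank_sub", "side": 3, "pos": pos, "to": f3[pos]})

                amplicon_seq = "".join(f5) + its2_seq + "".join(f3)
                sid = strain_id(li, ci, si)
                records.append(
                    RnaSequence(
                        id=sid,
                        residues=amplicon_seq,
                        clade_label=clade_name(li, ci),
                        source="synthetic",
                    )
                )
                strains.append(
                    StrainTruth(
                        id=sid,
                        lineage=li,
                        clade=ci,
                        its2_seq=its2_seq,
                        its2_db=db,
                        its2_start=len(f5),
                        its2_end=len(f5) + len(its2_seq),
                        amplicon_seq=amplicon_seq,
                        ops=ops,
                    )
                )

    truth = SyntheticTruth(
        seed=cfg.seed,
        template_seq=tseq.residues,
        template_db=tstruct.dotbracket,
        strains=strains,
        planted=resolved,
    )
    return records, truth


def replay_ledger(truth: SyntheticTruth, cfg: SimConfig, strain: StrainTruth) -> str:
    """Re-apply a strain's recorded ops to the template; must reproduce its ITS2."""
    tpl, _, _, _ = make_template(cfg)
    sites = _copy_sites(tpl.sites)
    by_tpos = {s.tpos: s for s in sites}
    for op in strain.ops:
        if op["op"] == "sub_pair":
            by_tpos[op["tpos5"]].char, by_tpos[op["tpos3"]].char = op["to"]
        elif op["op"] == "sub":
            by_tpos[op["tpos"]].char = op["to"]
        elif op["op"] == "del":
            members = [s for s in sites if s.region == op["region"]]
            for s in members[: op["n"]]:
                sites.remove(s)
        elif op["op"] == "ins":
            if op["region"] == "lineage_insertion":
                anchor = tpl.region_index["sp3"][0].tpos
                pos = next(i for i, s in enumerate(sites) if s.tpos == anchor)
            else:
                members = [s for s in sites if s.region == op["region"]]
                pos = sites.index(members[0])
            for c in op["chars"]:
                sites.insert(pos, _Site(c, op["region"], None))
        elif op["op"] == "flank_sub":
            pass  # flanks are outside the ITS2
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op['op']!r}")
    return "".join(s.char for s in sites)


def write_dataset(cfg: SimConfig, fasta_path: str | Path, truth_path: str | Path) -> None:
    records, truth = simulate(cfg)
    write_fasta(records, fasta_path)
    truth.to_json(truth_path)
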