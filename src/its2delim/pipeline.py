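"""End-to-end orchestration: extract -> fold/select -> align -> CBC -> distances -> report.

`analyze` is the in-memory pipeline over a list of amplicon (or pre-excised
ITS2) records; `run_pipeline` wraps it with file I/O, a declarative config
and a manifest so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cbc import CbcMatrix, cbc_matrix, consensus_pairs, lineage_diagnostic_cbcs
from .delimit_report import DelimitationCall, delimit, write_report
from .distances import (
    DistanceMatrix,
    between_group_distance,
    p_distance_matrix,
    within_group_distance,
)
from .formats_io import (
    RnaSequence,
    StructuredAlignment,
    read_fasta,
    write_fasta,
    write_structured_alignment,
    write_vienna,
)
from .hallmarks import HallmarkReport, select_structures_dataset
from .its2_extract import B9Helix, FlankModel, extract_its2
from .struct_align import AlignScoring, progressive_msa

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration for a pipeline run."""

    input_fasta: str | None = None
    out_dir: str = "its2_run"
    assume_its2: bool = False
    groups: dict | None = None  # strain id -> clade label (e.g. "A1"); None = use FASTA labels
    flank: FlankModel = field(default_factory=FlankModel)
    scoring: AlignScoring = field(default_factory=AlignScoring)
    min_frac: float = 0.9
    conservation: float = 0.7
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "flank" in raw:
            raw["flank"] = FlankModel(**raw["flank"])
        if "scoring" in raw:
            raw["scoring"] = AlignScoring(**raw["scoring"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, in memory."""

    its2: list  # RnaSequence
    b9: dict  # id -> B9Helix | None
    structures: dict  # id -> (SecondaryStructure, HallmarkReport)
    alignment: StructuredAlignment
    pairs: list  # ConsensusPair
    cbc_strains: CbcMatrix
    cbc_clades: CbcMatrix | None
    distances: DistanceMatrix
    diagnostic_bp: dict  # (lineage_a, lineage_b) -> [bp_id, ...]
    calls: list  # DelimitationCall
    clades: dict  # strain id -> clade label
    lineages: dict  # lineage label -> [strain ids]


def _clade_of(rec: RnaSequence, groups: dict | None) -> str:
    if groups is not None:
        if rec.id not in groups:
            raise ValueError(f"strain {rec.id!r} missing from groups")
        return groups[rec.id]
    if rec.clade_label:
        return rec.clade_label
    raise ValueError(f"no clade label for {rec.id!r}; supply a groups mapping")


def analyze(records: list[RnaSequence], cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full analysis on amplicon records.

    Clade labels are taken from ``cfg.groups`` or the records themselves;
    the first character of a clade label names its lineage (A1, A2 ... are
    clades of lineage A), mirroring the usual clade nomenclature.
    """
    cfg = cfg or RunConfig()
    if len(records) < 2:
        raise ValueError("the pipeline needs at least 2 sequences")
    clades = {rec.id: _clade_of(rec, cfg.groups) for rec in records}

    # 1. excision
    its2_records: list[RnaSequence] = []
    b9: dict[str, B9Helix | None] = {}
    for rec in records:
        its2, helix = extract_its2(rec, cfg.flank, assume_its2=cfg.assume_its2)
        its2_records.append(its2)
        b9[rec.id] = helix
    logger.info("extracted %d ITS2 sequences", len(its2_records))

    # 2. folding + hallmark/homology structure assignment
    structures = select_structures_dataset(its2_records)
    logger.info("assigned secondary structures")

    # 3. sequence+structure MSA
    aln = progressive_msa(
        [(seq, structures[seq.id][0]) for seq in its2_records], cfg.scoring
    )

    # 4. conserved pairs + CBC matrices
    lineage_of = {rid: clades[rid][0] for rid in aln.ids}
    pairs = consensus_pairs(
        aln, min_frac=cfg.min_frac, conservation=cfg.conservation, grouping=lineage_of
    )
    cbc_strains = cbc_matrix(aln, pairs)
    cbc_clades = cbc_matrix(aln, pairs, grouping=clades) if len(set(clades.values())) > 1 else None

    # 5. distances
    dm = p_distance_matrix(aln)

    # 6. lineage-diagnostic CBCs for every lineage pair
    lineages: dict[str, list[str]] = {}
    for rid in aln.ids:
        lineages.setdefault(lineage_of[rid], []).append(rid)
    diagnostic = {}
    lin_names = sorted(lineages)
    for i, la in enumerate(lin_names):
        for lb in lin_names[i + 1 :]:
            diagnostic[(la, lb)] = lineage_diagnostic_cbcs(
                aln, pairs, lineages[la], lineages[lb]
            )

    # 7. delimitation calls (strain level)
    calls = delimit(cbc_strains, dm_its2=dm)

    return PipelineResult(
        its2=its2_records,
        b9=b9,
        structures=structures,
        alignment=aln,
        pairs=pairs,
        cbc_strains=cbc_strains,
        cbc_clades=cbc_clades,
        distances=dm,
        diagnostic_bp=diagnostic,
        calls=calls,
        clades=clades,
        lineages=lineages,
    )


def lineage_specific_insertion(
    result: PipelineResult, lineage_a: str = "A", lineage_b: str = "B"
) -> tuple[int | None, int]:
    """Locate a lineage-B-specific spacer insertion 3' of helix III.

    Returns (0-based start column, length) of the longest contiguous run of
    alignment columns after the last helix-III consensus pair that are gap in
    every lineage-A row and occupied in at least one lineage-B row; (None, 0)
    if there is none.
    """
    aln = result.alignment
    rows_a = [aln.row(t) for t in result.lineages.get(lineage_a, [])]
    rows_b = [aln.row(t) for t in result.lineages.get(lineage_b, [])]
    if not rows_a or not rows_b:
        return None, 0
    h3_cols = [p.col3 for p in result.pairs if p.helix == "III"]
    start_from = (max(h3_cols) + 1) if h3_cols else 0
    best = (None, 0)
    run_start, run_len = None, 0
    for c in range(start_from, aln.n_cols):
        b_specific = all(r.residues[c] == "-" for r in rows_a) and any(
            r.residues[c] != "-" for r in rows_b
        )
        if b_specific:
            if run_start is None:
                run_start = c
            run_len += 1
            if run_len > best[1]:
                best = (run_start, run_len)
        else:
            run_start, run_len = None, 0
    return best


def _config_payload(cfg: RunConfig) -> dict:
    return {
        "input_fasta": cfg.input_fasta,
        "out_dir": cfg.out_dir,
        "assume_its2": cfg.assume_its2,
        "groups": cfg.groups,
        "flank": {"max_mismatch": cfg.flank.max_mismatch, "search_window": cfg.flank.search_window},
        "scoring": {
            "match": cfg.scoring.match,
            "mismatch": cfg.scoring.mismatch,
            "structure_state_mismatch_penalty": cfg.scoring.structure_state_mismatch_penalty,
            "gap_open": cfg.scoring.gap_open,
            "gap_extend": cfg.scoring.gap_extend,
        },
        "min_frac": cfg.min_frac,
        "conservation": cfg.conservation,
        "seed": cfg.seed,
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """File-level pipeline: read input, run `analyze`, write all stage outputs.

    The run directory contains per-stage outputs plus ``manifest.json``
    (package version, config and its hash) so identical config yields an
    identical manifest hash.
    """
    if not cfg.input_fasta:
        raise ValueError("config must name an input FASTA")
    in_path = Path(cfg.input_fasta)
    if not in_path.exists():
        raise FileNotFoundError(f"input FASTA {in_path} does not exist")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    records = read_fasta(in_path)
    if cfg.groups is not None:
        records = [
            RnaSequence(r.id, r.residues, clade_label=cfg.groups.get(r.id), source=r.source)
            for r in records
        ]
    result = analyze(records, cfg)

    write_fasta(result.its2, out / "its2.fasta")
    write_vienna([s for s, _rep in result.structures.values()], out / "structures.vienna")
    write_structured_alignment(result.alignment, out / "alignment.sa")

    import pandas as pd

    pd.DataFrame(
        result.cbc_strains.cbc, index=result.cbc_strains.taxa, columns=result.cbc_strains.taxa
    ).to_csv(out / "cbc_matrix.tsv", sep="\t")
    pd.DataFrame(
        result.cbc_strains.hcbc, index=result.cbc_strains.taxa, columns=result.cbc_strains.taxa
    ).to_csv(out / "hcbc_matrix.tsv", sep="\t")
    pd.DataFrame(
        result.distances.d, index=result.distances.taxa, columns=result.distances.taxa
    ).to_csv(out / "p_distances.tsv", sep="\t")
    pd.DataFrame(
        [
            {"bp_id": p.bp_id, "col5": p.col5 + 1, "col3": p.col3 + 1,
             "helix": p.helix, "support": p.support}
            for p in result.pairs
        ]
    ).to_csv(out / "consensus_pairs.tsv", sep="\t", index=False)
    with open(out / "diagnostic_cbcs.json", "w") as fh:
        json.dump({f"{a}x{b}": v for (a, b), v in result.diagnostic_bp.items()}, fh, indent=1)
    write_report(result.calls, out / "report.md")

    payload = _config_payload(cfg)
    manifest = {
        "version": __version__,
        "config": payload,
        "config_hash": hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest(),
        "n_records": len(records),
        "n_consensus_pairs": len(result.pairs),
        "n_sites_used": result.distances.n_sites_used,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
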