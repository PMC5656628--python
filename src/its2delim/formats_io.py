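"""Core sequence/structure containers and the plain-text formats the pipeline reads and writes.

Sequences live in :class:`RnaSequence` (RNA alphabet, ``T`` normalised to ``U``
on ingest), folded molecules in :class:`SecondaryStructure` (a partner table
equivalent to Vienna dot-bracket), and multiple alignments that carry a
structure state per residue in :class:`StructuredAlignment`.

Internally every coordinate is 0-based half-open; anything printed for a user
(position IDs, error columns) is 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Unpaired sentinel in partner tables.
UNPAIRED = -1

#: IUPAC nucleotide one-letter codes (RNA spelling).
IUPAC_CODES = frozenset("ACGURYSWKMBDHVN")

#: Concrete (unambiguous) RNA bases.
CONCRETE = frozenset("ACGU")

#: Base combinations allowed to pair (Watson-Crick + wobble).
VALID_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: Minimum number of unpaired residues enclosed by any base pair.
DEFAULT_MIN_LOOP = 3


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent containers."""


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA sequence over the IUPAC alphabet.

    ``T`` is normalised to ``U`` and case is folded to upper on construction,
    so downstream code only ever sees RNA spelling.
    """

    id: str
    residues: str
    clade_label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", norm)
        if not norm:
            raise FormatError(f"sequence {self.id!r}: empty residue string")
        for off, ch in enumerate(norm):
            if ch not in IUPAC_CODES:
                raise FormatError(
                    f"sequence {self.id!r}: non-IUPAC character {ch!r} at offset {off + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def with_id(self, new_id: str) -> "RnaSequence":
        return replace(self, id=new_id)


class SecondaryStructure:
    """A pseudoknot-free secondary structure as a partner table.

    ``partner[i]`` is the 0-based index that residue ``i`` pairs with, or
    :data:`UNPAIRED`.  The constructor enforces involution, no self-pairing,
    nestedness and the hairpin-loop minimum, so any instance reachable from
    user code is valid by construction.
    """

    def __init__(self, seq: RnaSequence, partner: Sequence[int], min_loop: int = DEFAULT_MIN_LOOP):
        self.seq = seq
        self.partner = np.asarray(partner, dtype=np.int64)
        self.min_loop = int(min_loop)
        self._validate()

    def _validate(self) -> None:
        n = len(self.seq)
        p = self.partner
        if p.shape != (n,):
            raise FormatError(
                f"structure for {self.seq.id!r}: partner table length {p.shape} != sequence length {n}"
            )
        paired = np.nonzero(p != UNPAIRED)[0]
        for i in paired:
            j = p[i]
            if j < 0 or j >= n:
                raise FormatError(f"structure for {self.seq.id!r}: partner index {j} out of range")
            if j == i:
                raise FormatError(f"structure for {self.seq.id!r}: self-pairing at {i + 1}")
            if p[j] != i:
                raise FormatError(
                    f"structure for {self.seq.id!r}: partner table not an involution at {i + 1}"
                )
            if i < j and j - i - 1 < self.min_loop:
                raise FormatError(
                    f"structure for {self.seq.id!r}: hairpin loop shorter than {self.min_loop} "
                    f"at pair ({i + 1},{j + 1})"
                )
        # nestedness: scan with a stack over opening/closing events
        stack: list[int] = []
        for i in range(n):
            j = p[i]
            if j == UNPAIRED:
                continue
            if i < j:
                stack.append(j)
            else:
                if not stack or stack[-1] != i:
                    raise FormatError(
                        f"structure for {self.seq.id!r}: crossing (pseudoknotted) pairs at {i + 1}"
                    )
                stack.pop()

    # -- constructors / views ------------------------------------------------

    @classmethod
    def all_unpaired(cls, seq: RnaSequence) -> "SecondaryStructure":
        return cls(seq, np.full(len(seq), UNPAIRED, dtype=np.int64))

    def pairs(self) -> list[tuple[int, int]]:
        """Ordered (i, j) with i < j."""
        return [(i, int(j)) for i, j in enumerate(self.partner) if j != UNPAIRED and i < j]

    @property
    def dotbracket(self) -> str:
        return render_dotbracket(self)

    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.partner != UNPAIRED)) // 2

    def __len__(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return self.seq.residues == other.seq.residues and np.array_equal(
            self.partner, other.partner
        )

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.seq.id!r}, {self.dotbracket!r})"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into :class:`RnaSequence` records.

    DNA spelling is accepted (``T`` becomes ``U``).  Duplicate ids are
    suffix-deduplicated (``x``, ``x_2``, ``x_3`` ...) with a warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    seen: dict[str, int] = {}
    out: list[RnaSequence] = []
    for rec in records:
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            warnings.warn(f"{path}: duplicate id {rid!r} renamed to {new_id!r}")
            logger.warning("duplicate FASTA id %r renamed to %r", rid, new_id)
            rid_out = new_id
        else:
            seen[rid] = 1
            rid_out = rid
        try:
            out.append(RnaSequence(id=rid_out, residues=str(rec.seq), source=str(path)))
        except FormatError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(records: Iterable[RnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# Vienna dot-bracket
# ---------------------------------------------------------------------------

def parse_dotbracket(db: str, seq: RnaSequence, min_loop: int = DEFAULT_MIN_LOOP) -> SecondaryStructure:
    """Parse a dot-bracket string (``.()`` only) against *seq*.

    Pseudoknot bracket layers (``[]{}<>``) are rejected: the structures this
    pipeline handles are nested.
    """
    if len(db) != len(seq):
        raise FormatError(
            f"dot-bracket length {len(db)} != sequence length {len(seq)} for {seq.id!r}"
        )
    partner = np.full(len(db), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for col, ch in enumerate(db):
        if ch == "(":
            stack.append(col)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced at column {col + 1}")
            i = stack.pop()
            partner[i], partner[col] = col, i
        elif ch != ".":
            raise FormatError(
                f"unsupported structure character {ch!r} at column {col + 1} "
                "(only '.', '(' and ')' are accepted)"
            )
    if stack:
        raise FormatError(f"unbalanced at column {len(db)}")
    return SecondaryStructure(seq, partner, min_loop=min_loop)


def render_dotbracket(structure: SecondaryStructure) -> str:
    out = []
    for i, j in enumerate(structure.partner):
        out.append("." if j == UNPAIRED else ("(" if i < j else ")"))
    return "".join(out)


def read_vienna(path: str | Path, min_loop: int = DEFAULT_MIN_LOOP) -> list[SecondaryStructure]:
    """Read a Vienna-style file: ``>id`` / sequence line / structure line."""
    path = Path(path)
    structures: list[SecondaryStructure] = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated record at line {i + 1}")
        rid = lines[i][1:].split()[0]
        seq = RnaSequence(id=rid, residues=lines[i + 1], source=str(path))
        structures.append(parse_dotbracket(lines[i + 2].split()[0], seq, min_loop=min_loop))
        i += 3
    return structures


def write_vienna(structures: Iterable[SecondaryStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.seq.id}\n{s.seq.residues}\n{s.dotbracket}\n")


# ---------------------------------------------------------------------------
# Structured alignment
# ---------------------------------------------------------------------------

GAP = "-"
#: per-residue structure states in an alignment row
STATE_CHARS = frozenset(".()-")


@dataclass(frozen=True)
class AlignedRow:
    """One alignment row: gapped residues plus per-residue structure states."""

    id: str
    residues: str  # gapped, over IUPAC + '-'
    states: str  # gapped, over '.', '(', ')', '-'

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.states):
            raise FormatError(
                f"row {self.id!r}: residue/structure length mismatch "
                f"({len(self.residues)} vs {len(self.states)})"
            )
        for c, (r, s) in enumerate(zip(self.residues, self.states)):
            if (r == GAP) != (s == GAP):
                raise FormatError(
                    f"row {self.id!r}: gap mismatch between residues and states at column {c + 1}"
                )
            if s not in STATE_CHARS:
                raise FormatError(f"row {self.id!r}: bad state char {s!r} at column {c + 1}")

    def degap(self, min_loop: int = DEFAULT_MIN_LOOP) -> SecondaryStructure:
        seq = RnaSequence(id=self.id, residues=self.residues.replace(GAP, ""))
        db = self.states.replace(GAP, "")
        return parse_dotbracket(db, seq, min_loop=min_loop)


class StructuredAlignment:
    """A multiple alignment whose rows carry residue and structure columns in lockstep."""

    def __init__(self, rows: Sequence[AlignedRow]):
        if not rows:
            raise FormatError("empty alignment")
        n_cols = len(rows[0].residues)
        for row in rows:
            if len(row.residues) != n_cols:
                raise FormatError(
                    f"row {row.id!r} has {len(row.residues)} columns, expected {n_cols}"
                )
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate row ids in alignment")
        self.rows = list(rows)
        self.n_cols = n_cols

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, rid: str) -> AlignedRow:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def residue_column(self, c: int) -> str:
        return "".join(r.residues[c] for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[AlignedRow]:
        return iter(self.rows)

    def subset(self, ids: Sequence[str]) -> "StructuredAlignment":
        return StructuredAlignment([self.row(i) for i in ids])


def write_structured_alignment(aln: StructuredAlignment, path: str | Path) -> None:
    """Write the paired residues+structure text format.

    Per row: a ``>id`` header, the gapped residue line, then the gapped
    structure-state line (gap columns carry ``-`` in both).  Round-trips
    losslessly with :func:`read_structured_alignment`.
    """
    with open(path, "w") as fh:
        for row in aln.rows:
            fh.write(f">{row.id}\n{row.residues}\n{row.states}\n")


def read_structured_alignment(path: str | Path) -> StructuredAlignment:
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty structured alignment")
    if len(lines) % 3 != 0:
        raise FormatError(f"{path}: expected triplets of header/residues/states lines")
    rows = []
    for i in range(0, len(lines), 3):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}: expected '>' header at line {i + 1}")
        rows.append(AlignedRow(id=lines[i][1:].split()[0], residues=lines[i + 1], states=lines[i + 2]))
    return StructuredAlignment(rows)
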