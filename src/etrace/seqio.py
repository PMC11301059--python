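"""Sequence and alignment handling.

Reads and writes FASTA (via Biopython), computes pairwise sequence
identity, greedily removes redundant sequences from an ortholog set, and
maps alignment columns onto the residue numbering of an ungapped
reference sequence (so a hit at alignment column 142 can be reported as,
say, A107 of human DJ-1 and H186 of E. coli HchA).

Conventions
-----------
* 20 standard amino-acid letters plus ``X`` (unknown); ``-`` is the gap.
* Input letters are normalised to upper case.
* ``X`` never counts as a match and is excluded from composition counts.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence as TSequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    DuplicateIdError,
    EtraceInputError,
    FastaParseError,
    GroupingError,
    UndefinedIdentityError,
    UnknownReferenceError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_VALID = set(AMINO_ACIDS) | {UNKNOWN, GAP}

IdentityMode = Literal["msa_columns", "global_align", "auto"]


@dataclass
class Sequence:
    """One protein sequence, possibly gapped if it comes from an alignment."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FastaParseError("sequence id must be non-empty")
        if not self.residues:
            raise FastaParseError(f"sequence {self.id!r} has no residues")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _VALID
        if bad:
            raise FastaParseError(
                f"sequence {self.id!r} contains invalid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered collection of equal-length gapped sequences."""

    sequences: list[Sequence]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offender = next(
                s.id for s in self.sequences if len(s) != len(self.sequences[0])
            )
            raise AlignmentError(
                f"aligned sequences have unequal lengths (e.g. {offender!r})"
            )
        _check_unique_ids(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, seq_id: str) -> Sequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise UnknownReferenceError(f"no sequence with id {seq_id!r}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


@dataclass
class GroupedAlignment:
    """A pooled alignment whose rows are labelled group A or group B.

    ``ref_a`` / ``ref_b`` name an optional reference sequence per group
    used only to translate alignment columns into residue numbering.
    """

    alignment: Alignment
    group_of: dict[str, str]
    ref_a: Optional[str] = None
    ref_b: Optional[str] = None

    def __post_init__(self):
        missing = [i for i in self.alignment.ids if i not in self.group_of]
        if missing:
            raise GroupingError(f"sequences without a group label: {missing}")
        bad = {g for g in self.group_of.values() if g not in ("A", "B")}
        if bad:
            raise GroupingError(f"group labels must be 'A' or 'B', got {sorted(bad)}")
        for grp in "AB":
            if not self.members(grp):
                raise GroupingError(f"group {grp} is empty")
        if self.ref_a is not None and self.group_of.get(self.ref_a) != "A":
            raise GroupingError(f"ref_a {self.ref_a!r} is not in group A")
        if self.ref_b is not None and self.group_of.get(self.ref_b) != "B":
            raise GroupingError(f"ref_b {self.ref_b!r} is not in group B")

    def members(self, group: str) -> list[Sequence]:
        return [s for s in self.alignment.sequences if self.group_of[s.id] == group]


@dataclass
class ColumnMap:
    """Maps each alignment column to a 1-based reference residue index.

    ``positions[c]`` is ``None`` where the reference carries a gap.
    """

    ref_id: str
    positions: list[Optional[int]] = field(default_factory=list)

    def residue_number(self, column: int) -> Optional[int]:
        """1-based column -> 1-based reference residue index or None."""
        return self.positions[column - 1]

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["column", "ref_residue_index"])
            for c, p in enumerate(self.positions, start=1):
                w.writerow([c, "gap" if p is None else p])


def _check_unique_ids(seqs: Iterable[Sequence]) -> None:
    seen = set()
    for s in seqs:
        if s.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {s.id!r}")
        seen.add(s.id)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, aligned: bool = False):
    """Read a FASTA file into Sequence objects (or an Alignment).

    Parameters
    ----------
    path : str or Path
        FASTA file.
    aligned : bool
        When True, enforce equal lengths and return an :class:`Alignment`.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}, line 1: expected '>' header, got {first[:30]!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    seqs = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        seqs.append(Sequence(id=rec.id, residues=str(rec.seq), description=desc))
    _check_unique_ids(seqs)
    if aligned:
        return Alignment(seqs)
    return seqs


def write_fasta(seqs, path, width: int = 60) -> None:
    """Write sequences (or an Alignment) to FASTA, wrapping at `width`."""
    if isinstance(seqs, Alignment):
        seqs = seqs.sequences
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_groups(path) -> dict[str, str]:
    """Read a 2-column TSV of ``sequence_id<TAB>A|B`` group labels."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("A", "B"):
                raise GroupingError(
                    f"{path}, line {lineno}: expected 'id<TAB>A|B', got {line!r}"
                )
            if parts[0] in labels:
                raise GroupingError(f"{path}, line {lineno}: duplicate id {parts[0]!r}")
            labels[parts[0]] = parts[1]
    if not labels:
        raise GroupingError(f"{path}: no group labels found")
    return labels


def write_groups(group_of: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, grp in group_of.items():
            fh.write(f"{sid}\t{grp}\n")


# ---------------------------------------------------------------------------
# Pairwise identity and redundancy filtering


def _column_identity(a: str, b: str) -> float:
    matches = 0
    occupied = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        occupied += 1
        if x == y and x != GAP and x != UNKNOWN:
            matches += 1
    if occupied == 0:
        raise UndefinedIdentityError(
            "identity undefined: no column carries a residue"
        )
    return matches / occupied


def _global_aligner() -> PairwiseAligner:
    # classic coarse protein identity scoring: match 1, mismatch 0,
    # gap open -10, gap extend -1
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(
    a: Sequence, b: Sequence, mode: IdentityMode = "msa_columns"
) -> float:
    """Fraction of identical residues between two sequences, in [0, 1].

    ``msa_columns`` compares aligned rows column-by-column (requires
    equal lengths); ``global_align`` first builds a global pairwise
    alignment of the ungapped sequences. In both, the denominator is the
    number of columns carrying at least one residue, and ``X`` never
    matches.
    """
    if mode == "auto":
        mode = "msa_columns" if len(a) == len(b) else "global_align"
    if mode == "msa_columns":
        if len(a) != len(b):
            raise AlignmentError(
                "msa_columns identity requires equal-length (aligned) sequences"
            )
        return _column_identity(a.residues, b.residues)
    if mode == "global_align":
        aln = _global_aligner().align(a.ungapped, b.ungapped)[0]
        return _column_identity(str(aln[0]), str(aln[1]))
    raise ValueError(f"unknown identity mode {mode!r}")


def redundancy_filter(
    seqs: TSequence[Sequence],
    max_identity: float,
    mode: IdentityMode = "auto",
) -> list[Sequence]:
    """Greedy longest-first redundancy removal.

    Sequences are sorted by descending ungapped length (ties broken by
    id, lexicographic); each is kept iff its identity to every
    already-kept sequence is strictly below ``max_identity``. The
    procedure is deterministic and seed-free. Used to emulate the
    "<40% mutual identity" construction of an ortholog set.
    """
    if not 0 < max_identity <= 1:
        raise EtraceInputError(f"max_identity must be in (0, 1], got {max_identity}")
    if not seqs:
        raise EtraceInputError("redundancy_filter needs at least one sequence")
    ordered = sorted(seqs, key=lambda s: (-len(s.ungapped), s.id))
    kept: list[Sequence] = []
    for cand in ordered:
        if all(pairwise_identity(cand, k, mode) < max_identity for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Column -> reference coordinate mapping


def column_to_reference_map(aln: Alignment, ref_id: str) -> ColumnMap:
    """Map alignment columns onto the reference's 1-based residue numbering.

    Column ``c`` maps to the count of non-gap reference letters in
    columns 1..c when the reference letter at ``c`` is not a gap, and to
    ``None`` (gap) otherwise.
    """
    ref = aln[ref_id]  # raises UnknownReferenceError
    positions: list[Optional[int]] = []
    counter = 0
    for letter in ref.residues:
        if letter == GAP:
            positions.append(None)
        else:
            counter += 1
            positions.append(counter)
    if counter == 0:
        warnings.warn(
            f"reference {ref_id!r} is all gaps; every column maps to 'gap'",
            stacklevel=2,
        )
    return ColumnMap(ref_id=ref_id, positions=positions)
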