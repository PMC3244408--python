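"""Sequence and transcript data model plus readers/writers.

Everything downstream (seed scanning, Tm calculation, expression
stratification) works on the small set of validated containers defined
here: plain nucleotide sequences with a declared alphabet, small-RNA
duplexes with designated guide/passenger strands, transcripts with an
optional CDS annotation that partitions them into 5'UTR / CDS / 3'UTR,
and promoters with a signed, TSS-relative coordinate system.

Coordinate conventions
----------------------
Transcript coordinates are 1-based and inclusive.  A CDS annotation
``(cds_start, cds_end)`` partitions the transcript exactly once into
5'UTR = [1, cds_start-1], CDS = [cds_start, cds_end] and
3'UTR = [cds_end+1, length]; empty UTRs are legal.  Promoter positions
are signed relative to the transcription start site: +1 is the TSS
itself, upstream positions are negative, and there is no position 0
(-1 abuts +1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class Alphabet(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


_ALPHABET_RESIDUES = {Alphabet.RNA: set("ACGU"), Alphabet.DNA: set("ACGT")}
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated, upper-case nucleotide string over a declared alphabet."""

    residues: str
    alphabet: Alphabet = Alphabet.RNA

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        alphabet = Alphabet(self.alphabet)
        object.__setattr__(self, "alphabet", alphabet)
        if not residues:
            raise ValidationError("empty sequence")
        allowed = _ALPHABET_RESIDUES[alphabet]
        for offset, ch in enumerate(residues):
            if ch not in allowed:
                raise ValidationError(
                    f"invalid {alphabet.value} residue {ch!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def reverse_complement(self) -> "NucleotideSequence":
        table = _RNA_COMPLEMENT if self.alphabet is Alphabet.RNA else _DNA_COMPLEMENT
        return NucleotideSequence(self.residues.translate(table)[::-1], self.alphabet)

    def as_rna(self) -> "NucleotideSequence":
        """Same residues read as RNA (T transcribed to U)."""
        if self.alphabet is Alphabet.RNA:
            return self
        return NucleotideSequence(self.residues.replace("T", "U"), Alphabet.RNA)

    def as_dna(self) -> "NucleotideSequence":
        if self.alphabet is Alphabet.DNA:
            return self
        return NucleotideSequence(self.residues.replace("U", "T"), Alphabet.DNA)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Reversed Watson-Crick complement, preserving the input alphabet."""
    return seq.reverse_complement()


@dataclass(frozen=True)
class SmallRNADuplex:
    """A named small-RNA duplex.

    ``strand_lower`` is the guide (antisense) strand, drawn at the lower
    side in duplex diagrams; ``strand_upper`` is the passenger (sense)
    strand.  The passenger may be absent: some mature miRNAs have no
    annotated star strand.
    """

    name: str
    strand_lower: NucleotideSequence
    strand_upper: Optional[NucleotideSequence] = None
    strand_labels: tuple[str, str] = ("sense", "antisense")

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("duplex name must be non-empty")
        for role, strand in (("upper", self.strand_upper), ("lower", self.strand_lower)):
            if strand is None:
                continue
            if strand.alphabet is not Alphabet.RNA:
                raise ValidationError(f"{self.name}: {role} strand must be RNA")
            if not 19 <= len(strand) <= 25:
                raise ValidationError(
                    f"{self.name}: {role} strand length {len(strand)} outside 19-25 nt"
                )

    def strand(self, role: "StrandRole") -> NucleotideSequence:
        role = StrandRole(role)
        if role is StrandRole.UPPER:
            if self.strand_upper is None:
                raise ValidationError(f"{self.name}: upper strand not annotated")
            return self.strand_upper
        return self.strand_lower


class StrandRole(str, Enum):
    UPPER = "upper"  # passenger / sense
    LOWER = "lower"  # guide / antisense


class Region(str, Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"
    UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with an optional 1-based inclusive CDS annotation."""

    transcript_id: str
    sequence: NucleotideSequence
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(
                f"{self.transcript_id}: cds_start and cds_end must be given together"
            )
        if self.cds_start is not None:
            if not 1 <= self.cds_start <= self.cds_end <= len(self.sequence):
                raise ValidationError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}] "
                    f"invalid for length {len(self.sequence)}"
                )

    @property
    def annotated(self) -> bool:
        return self.cds_start is not None

    def region_of(self, position: int) -> Region:
        """Region label of a 1-based transcript position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"{self.transcript_id}: position {position} outside [1, {len(self.sequence)}]"
            )
        if not self.annotated:
            return Region.UNANNOTATED
        if position < self.cds_start:
            return Region.UTR5
        if position <= self.cds_end:
            return Region.CDS
        return Region.UTR3

    def region_bounds(self, region: Region) -> tuple[int, int]:
        """1-based inclusive bounds of a region; (lo, hi) with hi < lo when empty."""
        if not self.annotated:
            raise ValidationError(f"{self.transcript_id}: no CDS annotation")
        length = len(self.sequence)
        return {
            Region.UTR5: (1, self.cds_start - 1),
            Region.CDS: (self.cds_start, self.cds_end),
            Region.UTR3: (self.cds_end + 1, length),
        }[Region(region)]


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence with the index of its +1 (TSS) position."""

    promoter_id: str
    sequence: NucleotideSequence
    tss_offset: int

    def __post_init__(self) -> None:
        if self.sequence.alphabet is not Alphabet.DNA:
            raise ValidationError(f"{self.promoter_id}: promoter must be DNA")
        if not 1 <= self.tss_offset <= len(self.sequence):
            raise ValidationError(
                f"{self.promoter_id}: tss_offset {self.tss_offset} outside sequence"
            )

    def signed_position(self, position: int) -> int:
        """Signed TSS-relative coordinate of a 1-based sequence position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"{self.promoter_id}: position {position} outside sequence"
            )
        if position >= self.tss_offset:
            return position - self.tss_offset + 1
        return position - self.tss_offset

    def unsigned_position(self, signed: int) -> int:
        """Inverse of :meth:`signed_position`."""
        if signed == 0:
            raise ValidationError("signed promoter coordinates have no position 0")
        position = self.tss_offset + signed - 1 if signed > 0 else self.tss_offset + signed
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(f"signed position {signed} outside sequence")
        return position


# ---------------------------------------------------------------------------
# Readers / writers


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[tuple[str, NucleotideSequence]]:
    """Read a multi-record FASTA file, validating residues against *alphabet*.

    Record order is preserved.  Raises :class:`ParseError` for malformed
    files and :class:`ValidationError` (naming the record and offset) for
    residues outside the alphabet.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    records: list[tuple[str, NucleotideSequence]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA header with empty identifier")
        try:
            seq = NucleotideSequence(str(rec.seq), alphabet)
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {rec.id!r}: {exc}") from exc
        records.append((rec.id, seq))
    return records


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, NucleotideSequence]], width: int = 60
) -> None:
    seqrecords = [
        SeqRecord(Seq(seq.residues), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 3:
        return False
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def read_region_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a tab-separated ``transcript_id  cds_start  cds_end`` table.

    A header row is optional and detected by a non-numeric second field.
    Bounds are validated as 1-based inclusive with start <= end; the
    upper bound against the transcript length is checked when records
    are attached to sequences (:func:`attach_regions`).
    """
    path = Path(path)
    mapping: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 tab-separated fields")
            tid = fields[0].strip()
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer CDS bound") from exc
            if tid in mapping:
                raise ValidationError(f"{path}: duplicate transcript id {tid!r}")
            if not 1 <= start <= end:
                raise ValidationError(
                    f"{path}: line {lineno}: invalid CDS bounds ({start}, {end})"
                )
            mapping[tid] = (start, end)
    return mapping


def attach_regions(
    fasta_records: Iterable[tuple[str, NucleotideSequence]],
    regions: Optional[dict[str, tuple[int, int]]] = None,
) -> list[TranscriptRecord]:
    """Join FASTA records with a CDS region table into TranscriptRecords.

    Transcripts absent from the table are left unannotated.
    """
    regions = regions or {}
    out = []
    for tid, seq in fasta_records:
        bounds = regions.get(tid)
        if bounds is None:
            out.append(TranscriptRecord(tid, seq))
        else:
            out.append(TranscriptRecord(tid, seq, bounds[0], bounds[1]))
    return out


def read_duplex_table(path: str | Path) -> list[SmallRNADuplex]:
    """Read small-RNA duplexes from a TSV.

    Columns: ``name  lower_strand  upper_strand  lower_label  upper_label``;
    upper strand and the labels are optional (empty or ``-`` means absent).
    The lower strand is the guide.
    """
    path = Path(path)
    duplexes: list[SmallRNADuplex] = []
    seen: set[str] = set()
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#") or not fields[0].strip():
                continue
            if lineno == 1 and fields[0].strip().lower() == "name":
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected at least 2 fields")
            name = fields[0].strip()
            if name in seen:
                raise ValidationError(f"{path}: duplicate duplex name {name!r}")
            seen.add(name)
            lower = NucleotideSequence(fields[1].strip(), Alphabet.RNA)
            upper_field = fields[2].strip() if len(fields) > 2 else ""
            upper = (
                NucleotideSequence(upper_field, Alphabet.RNA)
                if upper_field and upper_field != "-"
                else None
            )
            lower_label = fields[3].strip() if len(fields) > 3 and fields[3].strip() else "antisense"
            upper_label = fields[4].strip() if len(fields) > 4 and fields[4].strip() else "sense"
            duplexes.append(
                SmallRNADuplex(
                    name=name,
                    strand_lower=lower,
                    strand_upper=upper,
                    strand_labels=(upper_label, lower_label),
                )
            )
    return duplexes
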