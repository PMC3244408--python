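"""Seed extraction and complementary-site scanning, plus E-box motif scanning.

The seed of a RISC-loaded small-RNA strand is the heptamer at positions
2-8 from its 5' end (occasionally shifted to 1-7, as for miR-520f).  A
transcript is a potential off-target when it carries the exact
Watson-Crick reverse complement of that heptamer (the "target7").
Matching here is exact: no mismatches and no G:U wobble, and all
overlapping occurrences are reported.

Sites are serially named the way duplex site maps label them: the
numeric suffix of the duplex name, a strand letter ("s" for the upper /
sense strand, "a" for the lower / antisense strand) and a 5'->3' serial
number, e.g. "640a-1" for the first antisense-seed site of dsEcad640.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .sequences import (
    Alphabet,
    NucleotideSequence,
    PromoterRecord,
    Region,
    SmallRNADuplex,
    StrandRole,
    TranscriptRecord,
    ValidationError,
)


class SeedWindow(str, Enum):
    """Position window of the seed within a strand, counted from the 5' end."""

    POS2_8 = "pos2_8"
    POS1_7 = "pos1_7"


_WINDOW_SLICE = {SeedWindow.POS2_8: (1, 8), SeedWindow.POS1_7: (0, 7)}


@dataclass(frozen=True)
class SeedSpec:
    """A seed heptamer and the transcript 7-mer that betrays it."""

    duplex_name: str
    strand_role: StrandRole
    window: SeedWindow
    seed: str
    target7: str

    def __post_init__(self) -> None:
        if len(self.seed) != 7:
            raise ValidationError(f"seed must be 7 nt, got {self.seed!r}")
        expected = NucleotideSequence(self.seed, Alphabet.RNA).reverse_complement()
        if self.target7 != expected.residues:
            raise ValidationError(
                f"target7 {self.target7!r} is not the reverse complement of seed {self.seed!r}"
            )


@dataclass(frozen=True)
class SeedSite:
    """One exact seed-complementary match in a transcript."""

    transcript_id: str
    start: int  # 1-based position of the 5'-most matched nucleotide
    region: Region
    serial_name: str


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC-N DNA motif, default the E-box consensus CANNTG."""

    pattern: str = "CANNTG"
    name: str = "E-box"

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValidationError("motif pattern must be at least 4 nt")
        if not set(self.pattern.upper()) <= set("ACGTN"):
            raise ValidationError(f"motif pattern {self.pattern!r} not over ACGTN")
        object.__setattr__(self, "pattern", self.pattern.upper())


def extract_seed(
    duplex: SmallRNADuplex,
    strand_role: StrandRole = StrandRole.LOWER,
    window: SeedWindow = SeedWindow.POS2_8,
) -> SeedSpec:
    """Extract the seed heptamer of one duplex strand and precompute its target7."""
    strand_role = StrandRole(strand_role)
    window = SeedWindow(window)
    strand = duplex.strand(strand_role)
    lo, hi = _WINDOW_SLICE[window]
    if len(strand) < hi:
        raise ValidationError(
            f"{duplex.name} {strand_role.value} strand too short ({len(strand)} nt) "
            f"for window {window.value}"
        )
    seed = strand.residues[lo:hi]
    target7 = NucleotideSequence(seed, Alphabet.RNA).reverse_complement().residues
    return SeedSpec(
        duplex_name=duplex.name,
        strand_role=strand_role,
        window=window,
        seed=seed,
        target7=target7,
    )


def serial_prefix(duplex_name: str, strand_role: StrandRole) -> str:
    """Serial-name prefix: trailing digits of the duplex name (or the full
    name) plus the strand letter."""
    match = re.search(r"(\d+)$", duplex_name)
    stem = match.group(1) if match else duplex_name
    letter = "s" if StrandRole(strand_role) is StrandRole.UPPER else "a"
    return f"{stem}{letter}"


def find_overlapping(haystack: str, needle: str) -> list[int]:
    """All 0-based start offsets of *needle* in *haystack*, overlaps included."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_seed_sites(transcript: TranscriptRecord, spec: SeedSpec) -> list[SeedSite]:
    """Every exact occurrence of the seed's target7 in the transcript.

    DNA transcripts are matched after T->U normalization.  The region
    label is that of the site's 5'-most nucleotide; serial numbers run
    5'->3' and are dense.
    """
    haystack = transcript.sequence.as_rna().residues
    prefix = serial_prefix(spec.duplex_name, spec.strand_role)
    sites = []
    for k, offset in enumerate(find_overlapping(haystack, spec.target7), start=1):
        start = offset + 1
        sites.append(
            SeedSite(
                transcript_id=transcript.transcript_id,
                start=start,
                region=transcript.region_of(start),
                serial_name=f"{prefix}-{k}",
            )
        )
    return sites


_REGION_COLUMNS = [Region.UTR5, Region.CDS, Region.UTR3, Region.UNANNOTATED]


def census_seed_sites(
    transcripts: Sequence[TranscriptRecord],
    duplexes: Sequence[SmallRNADuplex],
    windows: Sequence[SeedWindow] = (SeedWindow.POS2_8,),
    strand_roles: Sequence[StrandRole] = (StrandRole.UPPER, StrandRole.LOWER),
) -> pd.DataFrame:
    """Per-(duplex, strand, window, transcript) counts of seed sites by region.

    Strands that are not annotated on a duplex are silently skipped.
    Rows are ordered deterministically by duplex name, strand, window
    and transcript id.
    """
    rows = []
    for duplex in sorted(duplexes, key=lambda d: d.name):
        for role in sorted(strand_roles, key=lambda r: StrandRole(r).value):
            if StrandRole(role) is StrandRole.UPPER and duplex.strand_upper is None:
                continue
            for window in windows:
                spec = extract_seed(duplex, role, window)
                for transcript in sorted(transcripts, key=lambda t: t.transcript_id):
                    sites = scan_seed_sites(transcript, spec)
                    counts = {region: 0 for region in _REGION_COLUMNS}
                    for site in sites:
                        counts[site.region] += 1
                    rows.append(
                        {
                            "duplex": duplex.name,
                            "strand": StrandRole(role).value,
                            "window": SeedWindow(window).value,
                            "seed": spec.seed,
                            "target7": spec.target7,
                            "transcript_id": transcript.transcript_id,
                            **{r.value: counts[r] for r in _REGION_COLUMNS},
                            "total": len(sites),
                        }
                    )
    columns = [
        "duplex",
        "strand",
        "window",
        "seed",
        "target7",
        "transcript_id",
        *[r.value for r in _REGION_COLUMNS],
        "total",
    ]
    return pd.DataFrame(rows, columns=columns)


def sites_table(
    transcripts: Sequence[TranscriptRecord],
    duplexes: Sequence[SmallRNADuplex],
    windows: Sequence[SeedWindow] = (SeedWindow.POS2_8,),
    strand_roles: Sequence[StrandRole] = (StrandRole.UPPER, StrandRole.LOWER),
) -> pd.DataFrame:
    """Flat per-site table matching :func:`census_seed_sites` inputs."""
    rows = []
    for duplex in sorted(duplexes, key=lambda d: d.name):
        for role in sorted(strand_roles, key=lambda r: StrandRole(r).value):
            if StrandRole(role) is StrandRole.UPPER and duplex.strand_upper is None:
                continue
            for window in windows:
                spec = extract_seed(duplex, role, window)
                for transcript in sorted(transcripts, key=lambda t: t.transcript_id):
                    for site in scan_seed_sites(transcript, spec):
                        rows.append(
                            {
                                "duplex": duplex.name,
                                "strand": StrandRole(role).value,
                                "window": SeedWindow(window).value,
                                "seed": spec.seed,
                                "target7": spec.target7,
                                "transcript_id": site.transcript_id,
                                "start": site.start,
                                "region": site.region.value,
                                "serial_name": site.serial_name,
                            }
                        )
    columns = [
        "duplex", "strand", "window", "seed", "target7",
        "transcript_id", "start", "region", "serial_name",
    ]
    return pd.DataFrame(rows, columns=columns)


def sites_to_bed(sites: Iterable[SeedSite]) -> list[str]:
    """BED6 lines (0-based half-open) for a list of sites."""
    return [
        f"{s.transcript_id}\t{s.start - 1}\t{s.start + 6}\t{s.serial_name}\t0\t."
        for s in sites
    ]


def _motif_regex(pattern: str) -> re.Pattern[str]:
    return re.compile("(?=(" + pattern.replace("N", "[ACGT]") + "))")


def scan_motif(
    promoter: PromoterRecord, motif: Optional[MotifSpec] = None
) -> list[tuple[int, str]]:
    """Forward-strand matches of an IUPAC-N motif in a promoter.

    Positions are signed TSS-relative coordinates of each match's
    5'-most nucleotide; overlapping matches are all reported.
    """
    motif = motif or MotifSpec()
    seq = promoter.sequence.residues
    out = []
    for m in _motif_regex(motif.pattern).finditer(seq):
        start = m.start() + 1
        out.append((promoter.signed_position(start), m.group(1)))
    return out
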