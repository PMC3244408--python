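"""Synthetic transcriptomes with planted seed sites and seed-shifted expression.

The generator emulates the structure of a genome-wide expression screen
for seed-dependent off-target silencing: tens of thousands of
transcripts, a small fraction carrying the seed-complementary 7-mer in
their 3'UTR, and several transfection conditions that share one guide
seed.  Carriers are shifted down in log2 fold change in every
condition; everything else is noise.

Two properties make the ground truth exact rather than probabilistic:
the planted 7-mer is rejection-resampled out of every non-planted
position (so non-carriers have zero sites anywhere, and carriers have
sites exactly where planted), and all randomness flows from a single
integer seed, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .scan import find_overlapping
from .sequences import (
    Alphabet,
    NucleotideSequence,
    SmallRNADuplex,
    TranscriptRecord,
    ValidationError,
    write_fasta,
)

_RNA_LOOKUP = np.frombuffer(b"ACGU", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for one synthetic off-target screen.

    Defaults mirror a whole-genome array screen of six small-RNA
    transfections sharing one guide seed: ~20k transcripts of which
    ~4.5% carry the seed-complementary 7-mer in their 3'UTR, a modest
    mean downshift per planted site, and near-half-unit log2 noise.
    """

    n_transcripts: int = 20_000
    utr5_length: int = 150
    cds_length: int = 900
    utr3_length: int = 600
    site_fraction: float = 0.045
    sites_per_carrier: int = 1                 # fixed count, used when no Poisson mean
    sites_poisson_mean: Optional[float] = 1.0  # truncated-Poisson >= 1; None = fixed
    effect_delta: float = 0.3     # mean log2FC downshift per planted site
    noise_sigma: float = 0.4      # log2FC standard deviation
    heavy_tailed: bool = False    # Student t (5 df) noise instead of Gaussian
    n_conditions: int = 6
    shared_seed: str = "AAGUGCU"  # guide seed shared by all conditions
    intensity_range: tuple[float, float] = (6.0, 14.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_transcripts", "utr5_length", "cds_length", "utr3_length", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.site_fraction < 1.0:
            raise ValidationError("site_fraction must be in [0, 1)")
        if self.noise_sigma <= 0:
            raise ValidationError("noise_sigma must be positive")
        if self.effect_delta < 0:
            raise ValidationError("effect_delta must be >= 0")
        if self.sites_per_carrier < 1:
            raise ValidationError("sites_per_carrier must be >= 1")
        if self.site_fraction > 0 and self.utr3_length < 7:
            raise ValidationError("utr3_length < 7 cannot host a planted site")
        seed = NucleotideSequence(self.shared_seed, Alphabet.RNA)
        if len(seed) != 7:
            raise ValidationError("shared_seed must be 7 nt")
        object.__setattr__(self, "shared_seed", seed.residues)

    @property
    def target7(self) -> str:
        return NucleotideSequence(self.shared_seed, Alphabet.RNA).reverse_complement().residues

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(f"cond{i + 1}" for i in range(self.n_conditions))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["intensity_range"] = list(self.intensity_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "intensity_range" in data:
            data["intensity_range"] = tuple(data["intensity_range"])
        return cls(**data)


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for a generated dataset."""

    all_ids: tuple[str, ...]
    carrier_ids: frozenset[str]
    planted_positions: dict[str, tuple[int, ...]]  # 1-based transcript starts
    true_shift: dict[str, float]                   # expected mean log2FC
    conditions: tuple[str, ...]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _RNA_LOOKUP[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _scrub(seq: str, target7: str, rng: np.random.Generator) -> str:
    """Rejection-resample every occurrence of target7 out of seq."""
    while True:
        hits = find_overlapping(seq, target7)
        if not hits:
            return seq
        chars = list(seq)
        for hit in hits:
            chars[hit : hit + 7] = _random_sequence(rng, 7)
        seq = "".join(chars)


def _draw_site_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.sites_poisson_mean is None:
        return config.sites_per_carrier
    while True:
        k = int(rng.poisson(config.sites_poisson_mean))
        if k >= 1:
            return k


def _place_sites(
    rng: np.random.Generator, utr3_start: int, utr3_length: int, k: int
) -> list[int]:
    """k non-overlapping 1-based 7-mer start positions inside the 3'UTR."""
    n_slots = utr3_length - 6
    reduced = n_slots - 6 * (k - 1)
    if reduced < k:
        raise ValidationError(
            f"3'UTR of {utr3_length} nt cannot host {k} non-overlapping sites"
        )
    picks = np.sort(rng.choice(reduced, size=k, replace=False))
    return [utr3_start + int(p) + 6 * i for i, p in enumerate(picks)]


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[tuple[str, NucleotideSequence]], dict[str, tuple[int, int]], SimulationTruth]:
    """Generate FASTA records, a CDS region table and the planted truth.

    Non-carriers contain no occurrence of the seed-complementary 7-mer
    anywhere; carriers contain it exactly at the recorded 3'UTR
    positions.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    target7 = config.target7
    length = config.utr5_length + config.cds_length + config.utr3_length
    cds_start = config.utr5_length + 1
    cds_end = config.utr5_length + config.cds_length
    width = max(5, len(str(config.n_transcripts)))

    records: list[tuple[str, NucleotideSequence]] = []
    regions: dict[str, tuple[int, int]] = {}
    carriers: set[str] = set()
    planted: dict[str, tuple[int, ...]] = {}
    shifts: dict[str, float] = {}

    is_carrier = rng.random(config.n_transcripts) < config.site_fraction
    for i in range(config.n_transcripts):
        tid = f"T{i + 1:0{width}d}"
        if is_carrier[i]:
            k = _draw_site_count(config, rng)
            while True:
                seq = _scrub(_random_sequence(rng, length), target7, rng)
                starts = _place_sites(rng, cds_end + 1, config.utr3_length, k)
                chars = list(seq)
                for start in starts:
                    chars[start - 1 : start + 6] = target7
                seq = "".join(chars)
                # planting can create junction artifacts; accept only exact truth
                if [h + 1 for h in find_overlapping(seq, target7)] == starts:
                    break
            carriers.add(tid)
            planted[tid] = tuple(starts)
            shifts[tid] = -config.effect_delta * k
        else:
            seq = _scrub(_random_sequence(rng, length), target7, rng)
            shifts[tid] = 0.0
        records.append((tid, NucleotideSequence(seq, Alphabet.RNA)))
        regions[tid] = (cds_start, cds_end)

    truth = SimulationTruth(
        all_ids=tuple(tid for tid, _ in records),
        carrier_ids=frozenset(carriers),
        planted_positions=planted,
        true_shift=shifts,
        conditions=config.conditions,
    )
    return records, regions, truth


def generate_expression(truth: SimulationTruth, config: SimulationConfig) -> pd.DataFrame:
    """Tidy expression table with seed-dependent downshifts planted.

    log2FC ~ Normal(true_shift, noise_sigma^2), independent across the
    conditions sharing the guide seed; with ``heavy_tailed`` the noise
    is Student t (5 df) rescaled to the same standard deviation.
    mean_intensity is uniform over the configured range.
    """
    rng = np.random.default_rng([config.rng_seed, 2])
    n = len(truth.all_ids)
    mu = np.array([truth.true_shift[tid] for tid in truth.all_ids])
    frames = []
    for condition in truth.conditions:
        if config.heavy_tailed:
            noise = rng.standard_t(5, size=n) * (config.noise_sigma / np.sqrt(5.0 / 3.0))
        else:
            noise = rng.normal(0.0, config.noise_sigma, size=n)
        intensity = rng.uniform(*config.intensity_range, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": truth.all_ids,
                    "condition": condition,
                    "log2_fold_change": mu + noise,
                    "mean_intensity": intensity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_table(truth: SimulationTruth) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": tid,
            "carrier": int(tid in truth.carrier_ids),
            "n_sites": len(truth.planted_positions.get(tid, ())),
            "positions": ",".join(map(str, truth.planted_positions.get(tid, ()))),
            "true_shift": truth.true_shift[tid],
        }
        for tid in truth.all_ids
    ]
    return pd.DataFrame(rows)


def write_bundle(out_dir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Generate a full dataset bundle on disk in the pipeline's own dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, regions, truth = generate_transcriptome(config)
    expression = generate_expression(truth, config)
    paths = {
        "transcripts": out / "transcripts.fasta",
        "regions": out / "regions.tsv",
        "expression": out / "expression.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
        "duplexes": out / "duplexes.tsv",
    }
    write_fasta(paths["transcripts"], records)
    with open(paths["regions"], "w") as handle:
        handle.write("transcript_id\tcds_start\tcds_end\n")
        for tid, (start, end) in regions.items():
            handle.write(f"{tid}\t{start}\t{end}\n")
    expression.to_csv(paths["expression"], sep="\t", index=False)
    truth_table(truth).to_csv(paths["truth"], sep="\t", index=False)
    config.to_yaml(paths["config"])
    rng = np.random.default_rng([config.rng_seed, 3])
    duplexes = [
        make_duplex(f"synth{i + 1:03d}", config.shared_seed, rng)
        for i in range(config.n_conditions)
    ]
    with open(paths["duplexes"], "w") as handle:
        handle.write("name\tlower_strand\tupper_strand\tlower_label\tupper_label\n")
        for d in duplexes:
            handle.write(
                f"{d.name}\t{d.strand_lower}\t{d.strand_upper}\t"
                f"{d.strand_labels[1]}\t{d.strand_labels[0]}\n"
            )
    return paths


def make_guide_with_seed(seed: str, rng: np.random.Generator, length: int = 21) -> str:
    """A synthetic guide strand carrying *seed* at positions 2-8."""
    if length < 8:
        raise ValidationError("guide length must be >= 8")
    return _random_sequence(rng, 1) + seed + _random_sequence(rng, length - 8)


def make_duplex(name: str, seed: str, rng: np.random.Generator) -> SmallRNADuplex:
    """A synthetic siRNA-like duplex whose guide carries *seed* at 2-8.

    The passenger strand is the reverse complement of guide positions
    3..21 plus a random 2-nt 3' overhang, the classic 19-bp duplex with
    2-nt overhangs.
    """
    guide = NucleotideSequence(make_guide_with_seed(seed, rng), Alphabet.RNA)
    core = NucleotideSequence(guide.residues[2:], Alphabet.RNA).reverse_complement()
    passenger = NucleotideSequence(core.residues + _random_sequence(rng, 2), Alphabet.RNA)
    return SmallRNADuplex(
        name=name,
        strand_lower=guide,
        strand_upper=passenger,
        strand_labels=("sense", "antisense"),
    )
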