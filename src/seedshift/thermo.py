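"""Nearest-neighbor melting temperature of the 7-bp seed duplex.

The thermodynamic stability of the duplex formed by a small-RNA seed
(positions 2-8, or 1-7, from the 5' end of the guide strand) and its
perfectly complementary target heptamer predicts the strength of
seed-dependent off-target silencing: high-Tm seeds silence strongly,
low-Tm seeds weakly.

The seed duplex is modeled as the heptamer paired with its exact
Watson-Crick complement — six propagation stacks plus a single helix
initiation term, no dangling ends.  The melting temperature of this
short duplex in a two-state model is

    Tm(°C) = 1000 * ΣΔH / (A + ΣΔS + R ln(CT/4)) − 273.15
             + 16.6 log10([Na+])

with ΣΔH (kcal/mol) and ΣΔS (cal/(K·mol)) summed over the six
nearest-neighbor stacks, A the helix initiation constant, R the gas
constant and CT the total strand concentration.  The shipped parameter
table is the Freier et al. (1986) RNA/RNA set with A = −10.8
cal/(K·mol), CT = 100 µM and [Na+] = 100 mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .scan import SeedWindow, extract_seed
from .sequences import Alphabet, NucleotideSequence, SmallRNADuplex, StrandRole, ValidationError


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor stack enthalpies/entropies plus duplex conditions."""

    dinucleotide_dH: dict[str, float]  # kcal/mol per 5'->3' stack
    dinucleotide_dS: dict[str, float]  # cal/(K*mol) per stack
    init_A: float = -10.8              # helix initiation, cal/(K*mol)
    gas_constant_R: float = 1.987      # cal/(K*mol)
    strand_conc_CT: float = 100e-6     # M total strand
    sodium_conc: float = 0.1           # M [Na+]

    def __post_init__(self) -> None:
        stacks = {a + b for a in "ACGU" for b in "ACGU"}
        for table_name, table in (
            ("dH", self.dinucleotide_dH),
            ("dS", self.dinucleotide_dS),
        ):
            missing = stacks - set(table)
            if missing:
                raise ValidationError(
                    f"{table_name} table missing stacks: {sorted(missing)}"
                )
        if self.strand_conc_CT <= 0 or self.sodium_conc <= 0:
            raise ValidationError("strand and sodium concentrations must be positive")


@dataclass(frozen=True)
class TmResult:
    seed: str
    sum_dH: float       # kcal/mol
    sum_dS: float       # cal/(K*mol)
    tm_celsius: float   # °C


def load_parameter_table(path: Optional[str | Path] = None, **conditions) -> NNParameterSet:
    """Load a stack -> (ΔH, ΔS) table from a plain-text TSV.

    With no path, the packaged Freier 1986 RNA/RNA table is used.
    Keyword overrides (init_A, strand_conc_CT, ...) are passed through
    to :class:`NNParameterSet`.
    """
    if path is None:
        source = resources.files("seedshift.data").joinpath("rna_nn_freier1986.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    dH: dict[str, float] = {}
    dS: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        stack, h, s = line.split("\t")
        dH[stack] = float(h)
        dS[stack] = float(s)
    return NNParameterSet(dinucleotide_dH=dH, dinucleotide_dS=dS, **conditions)


_DEFAULT_PARAMS: Optional[NNParameterSet] = None


def default_parameters() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_parameter_table()
    return _DEFAULT_PARAMS


def seed_duplex_tm(seed: str | NucleotideSequence, params: Optional[NNParameterSet] = None) -> TmResult:
    """Melting temperature of a 7-nt seed paired with its perfect complement."""
    params = params or default_parameters()
    seq = seed if isinstance(seed, NucleotideSequence) else NucleotideSequence(str(seed), Alphabet.RNA)
    residues = seq.as_rna().residues
    if len(residues) != 7:
        raise ValidationError(f"seed must be exactly 7 nt, got {len(residues)}")
    sum_dH = 0.0
    sum_dS = 0.0
    for i in range(6):
        stack = residues[i : i + 2]
        sum_dH += params.dinucleotide_dH[stack]
        sum_dS += params.dinucleotide_dS[stack]
    denom = params.init_A + sum_dS + params.gas_constant_R * math.log(
        params.strand_conc_CT / 4.0
    )
    tm = 1000.0 * sum_dH / denom - 273.15 + 16.6 * math.log10(params.sodium_conc)
    return TmResult(seed=residues, sum_dH=sum_dH, sum_dS=sum_dS, tm_celsius=tm)


def rank_strands_by_tm(
    duplexes: Sequence[SmallRNADuplex],
    params: Optional[NNParameterSet] = None,
    window: SeedWindow = SeedWindow.POS2_8,
    windows_by_strand: Optional[dict[tuple[str, StrandRole], SeedWindow]] = None,
) -> pd.DataFrame:
    """Per-strand seed Tm table, sorted by descending Tm.

    Ties are broken by duplex name then strand role.  A per-strand
    window override (``{(duplex_name, role): window}``) accommodates
    1-nt-shifted seeds such as miR-520f's 1-7 window.
    """
    params = params or default_parameters()
    windows_by_strand = windows_by_strand or {}
    rows = []
    for duplex in duplexes:
        for role in (StrandRole.UPPER, StrandRole.LOWER):
            if role is StrandRole.UPPER and duplex.strand_upper is None:
                continue
            w = windows_by_strand.get((duplex.name, role), window)
            spec = extract_seed(duplex, role, w)
            result = seed_duplex_tm(spec.seed, params)
            rows.append(
                {
                    "duplex": duplex.name,
                    "strand": role.value,
                    "window": SeedWindow(w).value,
                    "seed": spec.seed,
                    "target7": spec.target7,
                    "sum_dH": round(result.sum_dH, 2),
                    "sum_dS": round(result.sum_dS, 2),
                    "tm_celsius": round(result.tm_celsius, 1),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "duplex", "strand", "window", "seed", "target7",
            "sum_dH", "sum_dS", "tm_celsius",
        ],
    )
    return frame.sort_values(
        by=["tm_celsius", "duplex", "strand"], ascending=[False, True, True]
    ).reset_index(drop=True)
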