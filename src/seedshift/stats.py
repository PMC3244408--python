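"""Seed-stratified expression statistics.

Transcripts are split into seed-complementary targets and a
no-complementarity background, and the two log2 fold-change
distributions are compared: MA-plot tables, cumulative fractions, a
one-sided two-sample Kolmogorov-Smirnov test for the downward shift of
targets, pairwise correlations of common-seed target genes across
conditions, and a commonly-up/commonly-down classification across
conditions sharing one guide seed.

The one-sided K-S statistic for direction "down" is
``D = sup_x [F_targets(x) - F_background(x)]`` (targets stochastically
smaller pushes their ECDF up on the left), with the Smirnov asymptotic
tail probability ``p = exp(-2 D^2 m n / (m + n))`` clipped to (0, 1].
An exact permutation p-value is available for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sequences import Region, ValidationError

EXPRESSION_COLUMNS = ["transcript_id", "condition", "log2_fold_change", "mean_intensity"]


@dataclass(frozen=True)
class StratifiedSet:
    """Seed-carrying targets vs no-complementarity background for one seed."""

    condition: str
    target_ids: frozenset[str]
    background_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.target_ids & self.background_ids:
            raise ValidationError("target and background sets overlap")


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    m: int  # targets
    n: int  # background

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0:
            raise ValidationError(f"D={self.D} outside [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p={self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for calling a gene commonly decreased / increased."""

    down_threshold: float = 0.0
    up_threshold: float = 0.0
    require_all_conditions: bool = True

    def __post_init__(self) -> None:
        if self.down_threshold > self.up_threshold:
            raise ValidationError("down_threshold must be <= up_threshold")


# ---------------------------------------------------------------------------
# Expression table I/O


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a tidy expression TSV with columns transcript_id, condition,
    log2_fold_change, mean_intensity."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing expression columns {sorted(missing)}")
    values = frame[["log2_fold_change", "mean_intensity"]].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError(f"{path}: non-finite expression values")
    return frame[EXPRESSION_COLUMNS]


def write_expression(path: str | Path, frame: pd.DataFrame) -> None:
    frame[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def collapse_probes(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple probes per (transcript, condition) by median.

    Returns a frame with exactly one row per (transcript, condition).
    """
    if not frame.duplicated(subset=["transcript_id", "condition"]).any():
        return frame.reset_index(drop=True)
    return (
        frame.groupby(["transcript_id", "condition"], as_index=False)[
            ["log2_fold_change", "mean_intensity"]
        ].median()
    )


# ---------------------------------------------------------------------------
# Stratification


def stratify(
    records: pd.DataFrame,
    census: pd.DataFrame,
    condition: str,
    region: Region = Region.UTR3,
    min_sites: int = 1,
) -> StratifiedSet:
    """Split measured transcripts by seed complementarity.

    Targets carry at least *min_sites* sites in *region*; the background
    has no site in any region (the conservative reading of "no seed
    complementarity").  Transcripts with sites that do not meet the
    target rule belong to neither set.
    """
    region = Region(region)
    measured = set(records.loc[records["condition"] == condition, "transcript_id"])
    if not measured:
        raise ValidationError(f"no expression records for condition {condition!r}")
    census_measured = census[census["transcript_id"].isin(measured)]
    per_transcript = census_measured.groupby("transcript_id")[
        [Region.UTR5.value, Region.CDS.value, Region.UTR3.value, Region.UNANNOTATED.value, "total"]
    ].sum()
    uncensused = measured - set(per_transcript.index)
    if uncensused:
        raise ValidationError(
            f"census does not cover {len(uncensused)} measured transcripts "
            f"(e.g. {sorted(uncensused)[:3]})"
        )
    in_region = per_transcript[region.value]
    total = per_transcript["total"]
    targets = frozenset(per_transcript.index[in_region >= min_sites])
    background = frozenset(per_transcript.index[total == 0])
    if not targets:
        raise ValidationError("empty target set: statistics undefined")
    if not background:
        raise ValidationError("empty background set: statistics undefined")
    return StratifiedSet(condition=condition, target_ids=targets, background_ids=background)


# ---------------------------------------------------------------------------
# ECDF and the one-sided K-S test


def ecdf(values: Sequence[float]) -> list[tuple[float, float]]:
    """Right-continuous ECDF as sorted (value, cumulative fraction) pairs."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("ecdf of empty sample is undefined")
    uniq, counts = np.unique(arr, return_counts=True)
    fractions = np.cumsum(counts) / arr.size
    return list(zip(uniq.tolist(), fractions.tolist()))


def _ecdf_at(sample_sorted: np.ndarray, points: np.ndarray) -> np.ndarray:
    return np.searchsorted(sample_sorted, points, side="right") / sample_sorted.size


def _ks_D(targets: np.ndarray, background: np.ndarray) -> float:
    """sup_x [F_targets(x) - F_background(x)] over the pooled sample points."""
    t = np.sort(targets)
    b = np.sort(background)
    points = np.concatenate([t, b])
    diff = _ecdf_at(t, points) - _ecdf_at(b, points)
    return max(float(diff.max()), 0.0)


def ks_one_sided(
    targets: Sequence[float],
    background: Sequence[float],
    direction: str = "down",
) -> KSResult:
    """One-sided two-sample K-S test for a shifted target distribution.

    direction="down" tests whether targets are shifted toward lower
    values (their ECDF lies above the background's); "up" swaps roles.
    """
    t = np.asarray(targets, dtype=float)
    b = np.asarray(background, dtype=float)
    if t.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if direction == "down":
        D = _ks_D(t, b)
    elif direction == "up":
        D = _ks_D(-t, -b)
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    m, n = t.size, b.size
    p = math.exp(-2.0 * D * D * m * n / (m + n))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return KSResult(D=D, p_value=p, m=m, n=n)


def ks_permutation_pvalue(
    targets: Sequence[float],
    background: Sequence[float],
    direction: str = "down",
    max_exact: int = 100_000,
) -> float:
    """Exact permutation p-value for the one-sided K-S statistic.

    Enumerates every split of the pooled sample into groups of the
    observed sizes and returns the fraction with a statistic at least as
    large as observed.  Refuses pools with more than *max_exact* splits.
    """
    t = np.asarray(targets, dtype=float)
    b = np.asarray(background, dtype=float)
    observed = ks_one_sided(t, b, direction).D
    pooled = np.concatenate([t, b])
    m = t.size
    total = math.comb(pooled.size, m)
    if total > max_exact:
        raise ValidationError(
            f"{total} splits exceed max_exact={max_exact}; use the asymptotic p-value"
        )
    sign = 1.0 if direction == "down" else -1.0
    count = 0
    indices = range(pooled.size)
    for combo in itertools.combinations(indices, m):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        D = _ks_D(sign * pooled[mask], sign * pooled[~mask])
        if D >= observed - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Correlations and common up/down classification


def _fold_change_matrix(
    records: pd.DataFrame, gene_set: Iterable[str], conditions: Sequence[str]
) -> pd.DataFrame:
    """Genes x conditions matrix of log2FC restricted to *gene_set*."""
    gene_set = set(gene_set)
    collapsed = collapse_probes(records[records["transcript_id"].isin(gene_set)])
    matrix = collapsed.pivot(
        index="transcript_id", columns="condition", values="log2_fold_change"
    )
    missing_conditions = set(conditions) - set(matrix.columns)
    if missing_conditions:
        raise ValidationError(f"conditions not measured: {sorted(missing_conditions)}")
    matrix = matrix[list(conditions)]
    incomplete = matrix.index[matrix.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValidationError(
            f"{len(incomplete)} genes missing measurements (e.g. {incomplete[:5]})"
        )
    absent = gene_set - set(matrix.index)
    if absent:
        raise ValidationError(
            f"{len(absent)} genes not measured at all (e.g. {sorted(absent)[:5]})"
        )
    return matrix


def pairwise_correlation(
    records: pd.DataFrame,
    gene_set: Iterable[str],
    conditions: Sequence[str],
    method: str = "pearson",
) -> pd.DataFrame:
    """Condition-by-condition correlation matrix of log2FC over *gene_set*.

    Pearson by default (Spearman via ``method="spearman"``); the
    diagonal is exactly 1.  Zero variance in any condition is an error.
    """
    matrix = _fold_change_matrix(records, gene_set, conditions)
    if len(matrix) < 3:
        raise ValidationError("need at least 3 genes for a correlation")
    stds = matrix.std(ddof=0)
    flat = stds.index[stds == 0].tolist()
    if flat:
        raise ValidationError(f"zero fold-change variance in condition(s) {flat}")
    corr = matrix.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def classify_common(
    records: pd.DataFrame,
    gene_set: Iterable[str],
    conditions: Sequence[str],
    config: Optional[ClassificationConfig] = None,
) -> tuple[set[str], set[str], set[str]]:
    """Partition *gene_set* into commonly-down / commonly-up / neither.

    A gene is commonly down when its log2FC is below the down threshold
    in all conditions (or any condition, with
    ``require_all_conditions=False``); commonly up symmetrically.
    """
    config = config or ClassificationConfig()
    matrix = _fold_change_matrix(records, gene_set, conditions)
    below = matrix.lt(config.down_threshold)
    above = matrix.gt(config.up_threshold)
    if config.require_all_conditions:
        down_mask, up_mask = below.all(axis=1), above.all(axis=1)
    else:
        down_mask, up_mask = below.any(axis=1), above.any(axis=1)
    # a gene can satisfy both rules only with require_all=False and
    # mixed signs; commonly-down takes precedence for a clean partition
    up_mask &= ~down_mask
    down = set(matrix.index[down_mask])
    up = set(matrix.index[up_mask])
    neither = set(matrix.index) - down - up
    return down, up, neither


def ma_table(records: pd.DataFrame, strat: StratifiedSet) -> pd.DataFrame:
    """Plotting-ready MA table for one condition with a stratum flag.

    One row per record of the stratified condition: mean intensity (A),
    log2 fold change (M) and the stratum label ``target`` /
    ``background`` / ``other``.
    """
    sub = records[records["condition"] == strat.condition].copy()

    def flag(tid: str) -> str:
        if tid in strat.target_ids:
            return "target"
        if tid in strat.background_ids:
            return "background"
        return "other"

    sub["stratum"] = sub["transcript_id"].map(flag)
    return sub[["transcript_id", "mean_intensity", "log2_fold_change", "stratum"]].reset_index(
        drop=True
    )


def stratified_values(
    records: pd.DataFrame, strat: StratifiedSet
) -> tuple[np.ndarray, np.ndarray]:
    """(target, background) log2FC vectors for the stratified condition."""
    table = ma_table(collapse_probes(records), strat)
    t = table.loc[table["stratum"] == "target", "log2_fold_change"].to_numpy()
    b = table.loc[table["stratum"] == "background", "log2_fold_change"].to_numpy()
    return t, b


# ---------------------------------------------------------------------------
# Plots (two-panel layout: MA plot + cumulative fractions)


def plot_ma(table: pd.DataFrame, ax=None, title: str = ""):
    """MA scatter with background in grey, seed targets in red."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for stratum, color, size, z in (
        ("background", "0.7", 3, 1),
        ("other", "0.85", 3, 0),
        ("target", "crimson", 5, 2),
    ):
        sub = table[table["stratum"] == stratum]
        ax.scatter(
            sub["mean_intensity"], sub["log2_fold_change"],
            s=size, c=color, zorder=z, linewidths=0,
        )
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("mean intensity (log2)")
    ax.set_ylabel("log2 fold change")
    ax.set_title(title)
    return ax


def plot_cumulative(targets, background, ax=None, title: str = ""):
    """Cumulative-fraction curves of target vs background log2FC."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for values, color, label in (
        (background, "0.5", "no seed complementarity"),
        (targets, "crimson", "seed-complementary"),
    ):
        pairs = ecdf(values)
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        ax.step(xs, ys, where="post", color=color, label=label)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, loc="lower right")
    ax.set_title(title)
    return ax
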