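"""Stratification, ECDFs, the one-sided K-S test, correlations and
common up/down classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from seedshift import (
    ClassificationConfig,
    Region,
    ValidationError,
    classify_common,
    collapse_probes,
    ecdf,
    ks_one_sided,
    ks_permutation_pvalue,
    ma_table,
    pairwise_correlation,
    stratify,
    stratified_values,
)
from seedshift.stats import StratifiedSet

floats = st.floats(allow_nan=False, allow_infinity=False, width=32)


def expression_frame(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """{condition: {transcript: log2fc}} -> tidy frame with flat intensity."""
    rows = [
        {
            "transcript_id": tid,
            "condition": condition,
            "log2_fold_change": fc,
            "mean_intensity": 10.0,
        }
        for condition, series in values.items()
        for tid, fc in series.items()
    ]
    return pd.DataFrame(rows)


def census_frame(site_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """{transcript: {region: count}} -> census-like frame."""
    rows = []
    for tid, counts in site_counts.items():
        row = {r.value: 0 for r in Region}
        row.update(counts)
        row["transcript_id"] = tid
        row["total"] = sum(v for k, v in row.items() if k != "transcript_id")
        rows.append(row)
    return pd.DataFrame(rows)


class TestEcdf:
    def test_singleton(self):
        assert ecdf([0]) == [(0.0, 1.0)]

    def test_counting(self):
        assert ecdf([1, 2, 2, 4]) == [(1.0, 0.25), (2.0, 0.75), (4.0, 1.0)]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ecdf([])

    @given(st.lists(floats, min_size=1, max_size=50))
    def test_monotone_and_normalized(self, values):
        pairs = ecdf(values)
        fractions = [f for _, f in pairs]
        assert fractions == sorted(fractions)
        assert fractions[-1] == pytest.approx(1.0)
        xs = [x for x, _ in pairs]
        assert xs == sorted(xs)


class TestKSOneSided:
    def test_identical_samples(self):
        r = ks_one_sided([1, 2, 3], [1, 2, 3], "down")
        assert r.D == 0.0
        assert r.p_value == 1.0

    def test_separated_samples_worked_example(self):
        r = ks_one_sided([-3, -2, -1], [1, 2, 3], "down")
        assert r.D == 1.0
        assert r.p_value == pytest.approx(math.exp(-3))
        assert (r.m, r.n) == (3, 3)

    def test_permutation_cross_check(self):
        p = ks_permutation_pvalue([-3, -2, -1], [1, 2, 3], "down")
        assert p == pytest.approx(1 / 20)

    def test_up_direction_swaps_roles(self):
        down = ks_one_sided([-3, -2, -1], [1, 2, 3], "down")
        up = ks_one_sided([1, 2, 3], [-3, -2, -1], "up")
        assert up.D == down.D
        # and the mis-directed test sees nothing
        assert ks_one_sided([-3, -2, -1], [1, 2, 3], "up").D == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_one_sided([], [1.0], "down")

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
    )
    def test_matches_scipy_one_sided_statistic(self, t, b):
        mine = ks_one_sided(t, b, "down").D
        ref = sps.ks_2samp(t, b, alternative="greater").statistic
        assert mine == pytest.approx(ref, abs=1e-12)

    @given(
        st.lists(st.integers(-50, 50), min_size=3, max_size=30),
        st.lists(st.integers(-50, 50), min_size=3, max_size=30),
    )
    def test_rank_invariance_under_monotone_transform(self, t, b):
        """D depends only on ranks: a strictly monotone transform of
        both samples leaves it unchanged."""
        base = ks_one_sided(t, b, "down").D
        transformed = ks_one_sided(
            [math.exp(x / 10) for x in t], [math.exp(x / 10) for x in b], "down"
        ).D
        assert base == pytest.approx(transformed, abs=1e-12)

    def test_p_monotone_decreasing_in_D(self):
        ps = [
            math.exp(-2 * d * d * 100 * 100 / 200) for d in np.linspace(0, 1, 11)
        ]
        computed = []
        rng = np.random.default_rng(0)
        for shift in (0.0, 0.5, 1.0, 2.0):
            t = rng.normal(-shift, 1, 100)
            b = rng.normal(0, 1, 100)
            computed.append(ks_one_sided(t, b, "down"))
        for weak, strong in zip(computed, computed[1:]):
            if strong.D > weak.D:
                assert strong.p_value < weak.p_value
        assert ps == sorted(ps, reverse=True)


class TestStratify:
    def test_planted_split(self):
        records = expression_frame({"c1": {f"t{i}": 0.0 for i in range(1, 6)}})
        census = census_frame(
            {"t1": {"UTR3": 1}, "t2": {"UTR3": 2}, "t3": {}, "t4": {}, "t5": {}}
        )
        strat = stratify(records, census, "c1")
        assert strat.target_ids == {"t1", "t2"}
        assert strat.background_ids == {"t3", "t4", "t5"}

    def test_min_sites_can_empty_targets(self):
        records = expression_frame({"c1": {f"t{i}": 0.0 for i in range(1, 6)}})
        census = census_frame(
            {"t1": {"UTR3": 1}, "t2": {"UTR3": 1}, "t3": {}, "t4": {}, "t5": {}}
        )
        with pytest.raises(ValidationError):
            stratify(records, census, "c1", min_sites=2)

    def test_cds_only_carriers_in_neither_set(self):
        records = expression_frame({"c1": {"t1": 0.0, "t2": 0.0, "t3": 0.0}})
        census = census_frame({"t1": {"CDS": 2}, "t2": {"UTR3": 1}, "t3": {}})
        strat = stratify(records, census, "c1", region=Region.UTR3)
        assert strat.target_ids == {"t2"}
        assert "t1" not in strat.target_ids | strat.background_ids

    def test_uncensused_transcripts_rejected(self):
        records = expression_frame({"c1": {"t1": 0.0, "t2": 0.0}})
        census = census_frame({"t1": {"UTR3": 1}})
        with pytest.raises(ValidationError, match="census"):
            stratify(records, census, "c1")

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError):
            StratifiedSet("c1", frozenset({"a"}), frozenset({"a", "b"}))


class TestCorrelation:
    def frame(self):
        base = {"g1": -1.0, "g2": 0.5, "g3": 1.5, "g4": -0.25}
        return expression_frame(
            {
                "A": base,
                "B": base,  # exact copy
                "C": {k: -v for k, v in base.items()},  # exact negation
            }
        )

    def test_copy_and_negation(self):
        corr = pairwise_correlation(self.frame(), {"g1", "g2", "g3", "g4"}, ["A", "B", "C"])
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert corr.loc["A", "C"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([-1.0, 0.5, 1.5, -0.25])
        y = np.array([0.2, 0.1, 2.0, -0.8])
        records = expression_frame(
            {"A": dict(zip("g1 g2 g3 g4".split(), x)), "B": dict(zip("g1 g2 g3 g4".split(), y))}
        )
        xc, yc = x - x.mean(), y - y.mean()
        expected = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
        corr = pairwise_correlation(records, {"g1", "g2", "g3", "g4"}, ["A", "B"])
        assert corr.loc["A", "B"] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        genes = [f"g{i}" for i in range(8)]
        records = expression_frame(
            {c: dict(zip(genes, rng.normal(size=8))) for c in ["A", "B", "C", "D"]}
        )
        corr = pairwise_correlation(records, genes, ["A", "B", "C", "D"])
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert (corr.values >= -1 - 1e-12).all() and (corr.values <= 1 + 1e-12).all()

    def test_zero_variance_condition_named(self):
        records = expression_frame(
            {"A": {"g1": 1.0, "g2": 2.0, "g3": 3.0}, "flat": {"g1": 0.5, "g2": 0.5, "g3": 0.5}}
        )
        with pytest.raises(ValidationError, match="flat"):
            pairwise_correlation(records, {"g1", "g2", "g3"}, ["A", "flat"])

    def test_spearman_available(self):
        records = self.frame()
        corr = pairwise_correlation(records, {"g1", "g2", "g3", "g4"}, ["A", "C"], method="spearman")
        assert corr.loc["A", "C"] == pytest.approx(-1.0)


class TestClassifyCommon:
    conditions = [f"c{i}" for i in range(1, 7)]

    def test_uniformly_down(self):
        records = expression_frame({c: {"g1": -0.5} for c in self.conditions})
        down, up, neither = classify_common(records, {"g1"}, self.conditions)
        assert down == {"g1"} and not up and not neither

    def test_one_discordant_condition_breaks_commonality(self):
        values = {c: {"g1": -0.5} for c in self.conditions}
        values["c6"] = {"g1": 0.1}
        down, up, neither = classify_common(expression_frame(values), {"g1"}, self.conditions)
        assert neither == {"g1"}

    def test_planted_signs_recovered_exactly(self, rng):
        genes = [f"g{i}" for i in range(10)]
        signs = dict(zip(genes, [-1, -1, -1, 1, 1, 0, 0, -1, 1, 0]))
        values = {
            c: {
                g: signs[g] * (0.2 + rng.uniform(0, 0.5)) if signs[g] else rng.uniform(-0.4, 0.4)
                for g in genes
            }
            for c in self.conditions
        }
        # force "neither" genes to change sign across conditions
        for g in (g for g, s in signs.items() if s == 0):
            values["c1"][g] = 0.3
            values["c2"][g] = -0.3
        down, up, neither = classify_common(expression_frame(values), genes, self.conditions)
        assert down == {g for g, s in signs.items() if s == -1}
        assert up == {g for g, s in signs.items() if s == 1}
        assert neither == {g for g, s in signs.items() if s == 0}

    def test_partition_property(self, rng):
        genes = [f"g{i}" for i in range(25)]
        values = {c: dict(zip(genes, rng.normal(size=25))) for c in self.conditions}
        down, up, neither = classify_common(expression_frame(values), genes, self.conditions)
        assert down | up | neither == set(genes)
        assert not (down & up) and not (down & neither) and not (up & neither)

    def test_missing_measurement_listed(self):
        records = expression_frame({"c1": {"g1": 0.1, "g2": 0.2}, "c2": {"g1": 0.1}})
        with pytest.raises(ValidationError, match="g2"):
            classify_common(records, {"g1", "g2"}, ["c1", "c2"])

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValidationError):
            ClassificationConfig(down_threshold=0.5, up_threshold=-0.5)


class TestMaTable:
    def strat(self):
        return StratifiedSet("c1", frozenset({"t1"}), frozenset({"t2"}))

    def records(self):
        return expression_frame({"c1": {"t1": -0.4, "t2": 0.1, "t3": 0.2}})

    def test_rows_and_flags(self):
        table = ma_table(self.records(), self.strat())
        assert len(table) == 3
        flags = dict(zip(table["transcript_id"], table["stratum"]))
        assert flags == {"t1": "target", "t2": "background", "t3": "other"}

    def test_stratum_counts_conserved(self):
        table = ma_table(self.records(), self.strat())
        counts = table["stratum"].value_counts()
        assert counts["target"] == 1 and counts["background"] == 1

    def test_round_trip_values(self):
        records = self.records()
        table = ma_table(records, self.strat())
        merged = table.merge(records, on="transcript_id", suffixes=("", "_orig"))
        assert (merged["log2_fold_change"] == merged["log2_fold_change_orig"]).all()

    def test_stratified_values_split(self):
        t, b = stratified_values(self.records(), self.strat())
        assert t.tolist() == [-0.4]
        assert b.tolist() == [0.1]


class TestCollapseProbes:
    def test_median_collapse(self):
        frame = pd.DataFrame(
            {
                "transcript_id": ["t1"] * 3 + ["t2"],
                "condition": ["c1"] * 4,
                "log2_fold_change": [0.0, 1.0, 5.0, 2.0],
                "mean_intensity": [8.0, 9.0, 10.0, 11.0],
            }
        )
        collapsed = collapse_probes(frame)
        assert len(collapsed) == 2
        t1 = collapsed[collapsed["transcript_id"] == "t1"].iloc[0]
        assert t1["log2_fold_change"] == 1.0
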