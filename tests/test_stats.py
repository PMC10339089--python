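"""Paired tests, repeated-measures ANOVA and regression behavior."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_metric_table
from nirskinetics.stats import (
    paired_adjacent_tests,
    pre_post_tests,
    rm_anova_tissue_by_bedrest,
    simple_regression,
    validate_table,
)


def plateau_table(values_by_segment, n_subjects=3, tissue="tibia", channel="TSI"):
    rows = []
    for i in range(n_subjects):
        for seg_name, vals in values_by_segment.items():
            rows.append(
                dict(subject=f"s{i}", timepoint="PRE", tissue=tissue,
                     channel=channel, metric=f"plateau_{seg_name}",
                     value=vals[i])
            )
    return pd.DataFrame(rows)


class TestPairedAdjacent:
    def test_matches_hand_computed_t_statistic(self):
        # three subjects, baseline vs walk: differences d = (-6, -8, -10)
        base = [0.0, 0.0, 0.0]
        walk = [-6.0, -8.0, -10.0]
        table = plateau_table({
            "supine_baseline": base, "walk": walk,
            "stand": [0, 0, 0], "supine_end": [0, 0, 0],
        })
        res = [r for r in paired_adjacent_tests(table)
               if "supine_baseline vs walk" in r.comparison][0]
        d = np.array(walk) - np.array(base)
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(t_manual, rel=1e-12)
        assert res.mean_difference == pytest.approx(-8.0)
        assert res.family_size == 4
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 4))

    def test_identical_conditions_give_zero_difference_p_one(self):
        same = [4.0, 5.0, 6.0]
        table = plateau_table({
            "supine_baseline": same, "walk": same,
            "stand": same, "supine_end": same,
        })
        for res in paired_adjacent_tests(table):
            assert res.mean_difference == 0.0
            assert res.p_adjusted == 1.0

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(11)
        table = plateau_table({
            seg: rng.normal(0, 1, 5) for seg in
            ("supine_baseline", "walk", "stand", "supine_end")
        }, n_subjects=5)
        for res in paired_adjacent_tests(table):
            assert res.p_raw <= res.p_adjusted <= 1.0

    def test_power_to_detect_reported_walk_desaturation(self):
        """n = 11 cohort with the reported tibial walk TSI delta (-7.4, SD
        6.7) rejects the null after Bonferroni in most replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 50
        for _ in range(reps):
            base = np.zeros(11)
            walk = rng.normal(-7.4, 6.7, 11)
            table = plateau_table({
                "supine_baseline": base, "walk": walk,
                "stand": walk, "supine_end": base,
            }, n_subjects=11)
            res = [r for r in paired_adjacent_tests(table)
                   if "supine_baseline vs walk" in r.comparison][0]
            hits += res.p_adjusted < 0.05
        assert hits / reps >= 0.8

    def test_incomplete_pairs_dropped_with_log(self, caplog):
        table = plateau_table({
            "supine_baseline": [0, 0, 0], "walk": [-5, -6, -7],
            "stand": [1, 1, 1], "supine_end": [0, 0, 0],
        })
        table.loc[(table.subject == "s0") & (table.metric == "plateau_walk"),
                  "value"] = np.nan
        with caplog.at_level("INFO", logger="nirskinetics"):
            res = [r for r in paired_adjacent_tests(table)
                   if "supine_baseline vs walk" in r.comparison][0]
        assert res.n == 2

    def test_duplicate_rows_rejected(self):
        table = plateau_table({"supine_baseline": [0, 0, 0], "walk": [1, 1, 1],
                               "stand": [0, 0, 0], "supine_end": [0, 0, 0]})
        with pytest.raises(ValueError, match="duplicate"):
            validate_table(pd.concat([table, table.iloc[:1]], ignore_index=True))


class TestRmAnova:
    def test_identical_values_everywhere_null(self):
        rng = np.random.default_rng(0)
        table = make_metric_table(
            rng, 6,
            {(t, p): 0.0 for t in ("tibia", "gastrocnemius") for p in ("PRE", "POST")},
            {(t, p): 0.0 for t in ("tibia", "gastrocnemius") for p in ("PRE", "POST")},
        )
        table["value"] = 5.0
        res = rm_anova_tissue_by_bedrest(table, "m")
        for key in ("tissue", "bed_rest", "interaction"):
            assert res[key].statistic == pytest.approx(0.0, abs=1e-10)
            assert res[key].p_raw == pytest.approx(1.0)

    def test_pure_tissue_effect_detected(self):
        rng = np.random.default_rng(1)
        means = {("tibia", "PRE"): 125.4, ("tibia", "POST"): 125.4,
                 ("gastrocnemius", "PRE"): 55.0, ("gastrocnemius", "POST"): 55.0}
        sds = {k: 10.0 for k in means}
        table = make_metric_table(rng, 10, means, sds, subject_sd=15.0)
        res = rm_anova_tissue_by_bedrest(table, "m")
        assert res["tissue"].p_raw < 0.001
        assert res["bed_rest"].p_raw > 0.05

    def test_incomplete_subject_dropped(self):
        rng = np.random.default_rng(2)
        means = {(t, p): 1.0 for t in ("tibia", "gastrocnemius") for p in ("PRE", "POST")}
        sds = {k: 1.0 for k in means}
        table = make_metric_table(rng, 5, means, sds)
        table = table.drop(table[(table.subject == "s00")
                                 & (table.timepoint == "POST")
                                 & (table.tissue == "tibia")].index)
        res = rm_anova_tissue_by_bedrest(table, "m")
        assert res["tissue"].n == 4

    def test_missing_metric_rejected(self):
        rng = np.random.default_rng(3)
        table = make_metric_table(rng, 3, {("tibia", "PRE"): 0.0}, {("tibia", "PRE"): 1.0})
        with pytest.raises(ValueError, match="nope"):
            rm_anova_tissue_by_bedrest(table, "nope")


class TestPrePost:
    def test_known_shift_recovered(self):
        rng = np.random.default_rng(4)
        means = {("tibia", "PRE"): 10.0, ("tibia", "POST"): 7.0,
                 ("gastrocnemius", "PRE"): 10.0, ("gastrocnemius", "POST"): 10.0}
        sds = {k: 0.5 for k in means}
        table = make_metric_table(rng, 12, means, sds, subject_sd=2.0)
        res = {r.comparison: r for r in pre_post_tests(table, "m")}
        tib = res["tibia/TSI/m: POST vs PRE"]
        assert tib.mean_difference == pytest.approx(-3.0, abs=0.5)
        assert tib.p_raw < 0.001


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, r2 = simple_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_hand_computed_ols(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 8.0])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope_manual = sxy / sxx
        r2_manual = sxy**2 / (sxx * np.sum((y - y.mean()) ** 2))
        slope, r2 = simple_regression(x, y)
        assert slope == pytest.approx(slope_manual, rel=1e-12)
        assert r2 == pytest.approx(r2_manual, rel=1e-12)

    def test_independent_data_near_zero_r2(self):
        rng = np.random.default_rng(5)
        slope, r2 = simple_regression(rng.normal(size=1000), rng.normal(size=1000))
        assert r2 < 0.01

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            simple_regression([1.0, 2.0], [1.0, 2.0])
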