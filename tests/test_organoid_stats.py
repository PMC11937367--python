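"""Unit and property tests for organoid assay statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from secrepair.organoids import (
    OrganoidAssay,
    OrganoidExperiment,
    anova_dunnett,
    bonferroni_alpha,
    cfe,
    dunnett_max_abs_t_sf,
    effect_estimate,
    filter_diameters,
    ks_two_sample,
    normality_battery,
    organoid_type_proportions,
)
from secrepair.simulate import OrganoidFixtureConfig, generate_organoid_experiment


def brute_force_ks_d(x, y):
    """sup over all thresholds of |ECDF_x - ECDF_y| by direct enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        best = max(best, abs((x <= t).mean() - (y <= t).mean()))
    return best


class TestCfe:
    def test_arithmetic(self):
        assert cfe(0, 10000) == 0.0
        assert cfe(120, 10000) == pytest.approx(1.2)

    def test_zero_seeded_errors(self):
        with pytest.raises(ValueError):
            cfe(5, 0)

    @given(k=st.integers(1, 50), n_org=st.integers(0, 500))
    @settings(derandomize=True, max_examples=40)
    def test_scale_free(self, k, n_org):
        assert cfe(k * n_org, k * 10000) == pytest.approx(cfe(n_org, 10000))

    def test_binomial_expectation(self):
        # empirical CFE over many seeds converges to the configured rate
        vals = []
        for seed in range(50):
            cfg = OrganoidFixtureConfig(seed=seed, baseline_cfe=0.02,
                                        n_replicates=1)
            exps, _ = generate_organoid_experiment(cfg)
            ctrl = [e for e in exps if e.condition == "control"][0]
            vals.append(ctrl.cfe_percent)
        se = 100 * math.sqrt(0.02 * 0.98 / 10000) / math.sqrt(50)
        assert abs(np.mean(vals) - 2.0) < 3 * se


class TestDiameterFilter:
    def test_strict_threshold(self):
        assert filter_diameters([30, 50, 51, 400]) == [51, 400]

    def test_empty(self):
        assert filter_diameters([]) == []

    def test_matches_direct_count(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 200, 300).tolist()
        assert len(filter_diameters(vals)) == sum(v > 50 for v in vals)


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_fully_separated(self):
        d, _ = ks_two_sample([1, 2], [5, 6])
        assert d == 1.0

    def test_small_example(self):
        d, _ = ks_two_sample([1, 2], [1, 3])
        assert d == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @given(
        x=st.lists(st.sampled_from([1.0, 2.0, 3.0, 4.0]), min_size=1, max_size=5),
        y=st.lists(st.sampled_from([1.0, 2.0, 3.0, 4.0]), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=80)
    def test_matches_bruteforce_and_monotone_invariance(self, x, y):
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(brute_force_ks_d(x, y))
        fx = [math.exp(v) for v in x]
        fy = [math.exp(v) for v in y]
        d2, _ = ks_two_sample(fx, fy)
        assert d2 == pytest.approx(d)


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,display", [(3, "0.0167"), (4, "0.0125"), (12, "0.004"),
                      (20, "0.0025"), (2, "0.025")]
    )
    def test_legend_display_values(self, m, display):
        alpha, shown = bonferroni_alpha(0.05, m)
        assert shown == display
        assert alpha == pytest.approx(0.05 / m)

    def test_identity_and_monotonicity(self):
        assert bonferroni_alpha(0.05, 1)[0] == 0.05
        alphas = [bonferroni_alpha(0.05, m)[0] for m in range(1, 20)]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_zero_comparisons_errors(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestNormalityBattery:
    def test_normal_sample_is_parametric(self):
        x = np.random.default_rng(11).normal(0, 1, 500)
        verdicts, parametric = normality_battery(x)
        assert parametric
        assert len(verdicts) == 4

    def test_exponential_sample_is_nonparametric(self):
        x = np.random.default_rng(11).exponential(1, 500)
        _, parametric = normality_battery(x)
        assert not parametric

    def test_small_sample_errors(self):
        with pytest.raises(ValueError, match="n >= 8"):
            normality_battery([1, 2, 3, 4, 5])


class TestDunnett:
    def test_identical_constants_give_p_one(self):
        groups = {"c": [5.0] * 4, "a": [5.0] * 4, "b": [5.0] * 4}
        for paired in (False, True):
            res = anova_dunnett(groups, "c", paired=paired)
            assert all(r.p_adjusted == 1.0 for r in res)

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        groups = {
            "c": (rng.normal(0, 0.01, 6)).tolist(),
            "t": (rng.normal(10, 0.01, 6)).tolist(),
        }
        res = anova_dunnett(groups, "c")
        assert res[0].p_adjusted < 1e-4

    def test_single_comparison_close_to_t_test(self):
        rng = np.random.default_rng(5)
        groups = {"c": rng.normal(0, 1, 8).tolist(),
                  "t": rng.normal(1, 1, 8).tolist()}
        res = anova_dunnett(groups, "c")
        _, p_t = stats.ttest_ind(groups["t"], groups["c"])
        assert res[0].p_adjusted == pytest.approx(p_t, rel=0.10)

    def test_paired_adjustment_matches_scipy_distribution(self):
        """The equicorrelated max-|t| integral agrees with scipy's Dunnett
        distribution for a balanced unpaired design (same rho = 1/2)."""
        rng = np.random.default_rng(3)
        n, k = 10, 3
        samples = [rng.normal(0.5 * i, 1, n) for i in range(1, k + 1)]
        control = rng.normal(0, 1, n)
        res = stats.dunnett(*samples, control=control, random_state=1)
        df = (k + 1) * n - (k + 1)
        for t_stat, p_scipy in zip(res.statistic, res.pvalue):
            p_mine = dunnett_max_abs_t_sf(abs(float(t_stat)), k, df)
            assert p_mine == pytest.approx(p_scipy, abs=5e-3)

    def test_paired_reduces_to_t_for_single_comparison(self):
        rng = np.random.default_rng(9)
        c = rng.normal(0, 1, 8)
        t = c + rng.normal(0.8, 0.5, 8)
        res = anova_dunnett({"c": c.tolist(), "t": t.tolist()}, "c", paired=True)
        _, p_ref = stats.ttest_rel(t, c)
        assert res[0].p_adjusted == pytest.approx(p_ref, rel=0.02)

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            anova_dunnett({"a": [1, 2]}, "c")

    def test_paired_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="equal"):
            anova_dunnett({"c": [1, 2, 3], "a": [1, 2]}, "c", paired=True)


def _experiment(cond, rid, n_org, n_seeded=10000):
    return OrganoidExperiment(condition=cond, replicate_id=rid,
                              n_seeded=n_seeded, n_organoids=n_org)


class TestEffectEstimate:
    def test_exact_ratio_gives_exact_percent(self):
        ctrl = [_experiment("c", f"R{i}", 100) for i in range(4)]
        trt = [_experiment("t", f"R{i}", 175) for i in range(4)]
        mean, (lo, hi), _ = effect_estimate(trt, ctrl)
        assert mean == pytest.approx(75.0)
        assert lo == pytest.approx(75.0) and hi == pytest.approx(75.0)

    def test_no_change_gives_zero(self):
        ctrl = [_experiment("c", f"R{i}", 90 + i) for i in range(3)]
        trt = [_experiment("t", f"R{i}", 90 + i) for i in range(3)]
        mean, _, _ = effect_estimate(trt, ctrl)
        assert mean == pytest.approx(0.0)

    def test_zero_control_pair_excluded_with_warning(self):
        ctrl = [_experiment("c", "R0", 0), _experiment("c", "R1", 100)]
        trt = [_experiment("t", "R0", 50), _experiment("t", "R1", 150)]
        with pytest.warns(UserWarning, match="excluded"):
            mean, _, table = effect_estimate(trt, ctrl)
        assert len(table) == 1 and mean == pytest.approx(50.0)

    def test_all_pairs_excluded_errors(self):
        ctrl = [_experiment("c", "R0", 0)]
        trt = [_experiment("t", "R0", 10)]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="excluded"):
                effect_estimate(trt, ctrl)

    @pytest.mark.parametrize("ratio", [1.0, 1.5, 1.75, 2.0])
    def test_recovers_planted_ratio_grid(self, ratio):
        """Mean recovered effect across 50 seeds is within 2 percentage
        points of the planted percent change at n_seeded = 10,000."""
        means = []
        for seed in range(50):
            cfg = OrganoidFixtureConfig(
                seed=seed, treatment_cfe_ratio=ratio, n_replicates=4
            )
            exps, _ = generate_organoid_experiment(cfg)
            trt = [e for e in exps if e.condition == "treated"]
            ctrl = [e for e in exps if e.condition == "control"]
            mean, _, _ = effect_estimate(trt, ctrl, n_boot=10, seed=seed)
            means.append(mean)
        assert abs(np.mean(means) - 100 * (ratio - 1)) < 2.0


class TestTypeProportions:
    def test_example(self):
        got = organoid_type_proportions(
            {"SPC+": 6, "ACT+": 2, "SPC+/ACT+": 1, "SPC-/ACT-": 1}
        )
        assert got == {"SPC+": 60, "ACT+": 20, "SPC+/ACT+": 10, "SPC-/ACT-": 10}

    def test_single_category(self):
        assert organoid_type_proportions({"SPC+": 7})["SPC+"] == 100.0

    @given(counts=st.lists(st.integers(0, 30), min_size=2, max_size=4))
    @settings(derandomize=True, max_examples=40)
    def test_conservation(self, counts):
        if sum(counts) == 0:
            with pytest.raises(ValueError):
                organoid_type_proportions(dict(enumerate(counts)))
            return
        got = organoid_type_proportions(dict(enumerate(counts)))
        assert sum(got.values()) == pytest.approx(100.0, abs=1e-9)


class TestOrganoidAssay:
    def test_fit_summary_end_to_end(self):
        cfg = OrganoidFixtureConfig(seed=2, n_replicates=6, include_cse=True)
        exps, truth = generate_organoid_experiment(cfg)
        res = OrganoidAssay(exps, control="control", paired=True).fit()
        text = res.summary()
        assert "treated" in text and "cse" in text
        # the planted 75% boost should register as a positive effect
        assert res.effects["treated"]["mean_percent_change"] > 25
        # CSE suppression should point the other way
        assert res.effects["cse"]["mean_percent_change"] < 0
        # diameter KS comparisons carry the Bonferroni alpha for m=2
        assert res.alpha_adjusted_display == "0.025"

    def test_from_dataframe_roundtrip(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "condition": ["control", "treated"] * 2,
                "replicate_id": ["R1", "R1", "R2", "R2"],
                "n_seeded": [10000] * 4,
                "n_organoids": [100, 170, 110, 180],
            }
        )
        diams = pd.DataFrame(
            {
                "condition": ["control"] * 3 + ["treated"] * 3,
                "replicate_id": ["R1"] * 3 + ["R1"] * 3,
                "diameter_um": [80, 120, 45, 90, 130, 200],
            }
        )
        assay = OrganoidAssay.from_dataframe(counts, diams, control="control",
                                             paired=True)
        res = assay.fit()
        assert res.effects["treated"]["mean_percent_change"] > 0
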