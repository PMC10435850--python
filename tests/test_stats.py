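import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import swallowsound as ss
from swallowsound.stats import StatsError


class TestCompareGroups:
    def test_identical_groups_yield_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = ss.compare_groups(a, a.copy(), "continuous")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(10, 1, 200)
        _, p = ss.compare_groups(a, b, "continuous")
        assert p < 1e-6

    def test_chi_square_extreme_table(self):
        a = ["x"] * 50
        b = ["y"] * 50
        chi2, p = ss.compare_groups(a, b, "categorical")
        assert p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError, match="variance"):
            ss.compare_groups([1.0, 1.0], [1.0, 1.0], "continuous")


class TestUnivariateScreen:
    def test_perfect_factor_selected(self):
        cohort, _ = ss.synth_cohort(ss.SyntheticCohortSpec(n_patients=40, seed=1))
        cohort["mirror"] = cohort["index"]
        table, selected = ss.univariate_screen(cohort, ["mirror", "age"])
        assert table.loc[table.factor == "mirror", "univariate_p"].iloc[0] < 1e-12
        assert "mirror" in selected

    def test_age_always_carried_forward(self):
        # a cohort whose index does not depend on age at all
        cohort, _ = ss.synth_cohort(
            ss.SyntheticCohortSpec(n_patients=40, betas={}, intercept=0.2, seed=2)
        )
        table, selected = ss.univariate_screen(cohort, ss.DEFAULT_FACTORS)
        assert "age" in selected

    def test_null_type_one_error_near_nominal(self):
        """Under a simulated null the 5% screen rejects ~5% of the time
        (within 3 binomial standard errors over the replicates)."""
        n_rep, hits = 1_000, 0
        for r in range(n_rep):
            cohort, _ = ss.synth_cohort(
                ss.SyntheticCohortSpec(n_patients=24, betas={}, intercept=0.21,
                                       sigma=0.06, seed=50_000 + r)
            )
            table, _ = ss.univariate_screen(cohort, ["tongue_pressure"])
            hits += int(table["univariate_p"].iloc[0] < 0.05)
        rate = hits / n_rep
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < band

    def test_constant_factor_rejected(self):
        cohort, _ = ss.synth_cohort(ss.SyntheticCohortSpec(n_patients=10, seed=3))
        cohort["flat"] = 1.0
        with pytest.raises(StatsError, match="constant"):
            ss.univariate_screen(cohort, ["flat"])


class TestAdjustedModel:
    def test_recovers_planted_coefficient(self):
        spec = ss.SyntheticCohortSpec(n_patients=500, sigma=0.02, seed=4)
        cohort, truth = ss.synth_cohort(spec)
        res = ss.adjusted_model(cohort, "alsfrs_r_total")
        beta = truth["betas"]["alsfrs_r_total"]
        assert res.ci_low <= beta <= res.ci_high
        assert res.coefficient == pytest.approx(beta, abs=5e-4)
        assert res.p_value < 1e-6

    def test_null_factor_ci_covers_zero(self):
        cohort, _ = ss.synth_cohort(
            ss.SyntheticCohortSpec(n_patients=500, betas={}, intercept=0.2,
                                   sigma=0.05, seed=6)
        )
        res = ss.adjusted_model(cohort, "tongue_pressure")
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_age_duplicate_collinearity_rejected(self):
        cohort, _ = ss.synth_cohort(ss.SyntheticCohortSpec(n_patients=30, seed=7))
        cohort["age_copy"] = cohort["age"]
        with pytest.raises(StatsError, match="collinear"):
            ss.adjusted_model(cohort, "age_copy")

    def test_logistic_family_runs(self):
        cohort, _ = ss.synth_cohort(ss.SyntheticCohortSpec(n_patients=200, seed=8))
        res = ss.adjusted_model(cohort, "alsfrs_r_total", family="logistic",
                                outcome_cutoff=float(cohort["index"].median()))
        assert res.ci_low <= res.coefficient <= res.ci_high

    def test_two_step_table_has_one_row_per_factor(self):
        cohort, _ = ss.synth_cohort(ss.SyntheticCohortSpec(n_patients=100, seed=9))
        table = ss.two_step_analysis(cohort)
        assert list(table["factor"]) == list(ss.DEFAULT_FACTORS)
        sel = table.dropna(subset=["coefficient"]) if "coefficient" in table else table
        assert (sel["ci_low"] <= sel["coefficient"]).all()
        assert (sel["coefficient"] <= sel["ci_high"]).all()


class TestRoc:
    def test_perfect_separation(self):
        idx = np.concatenate([np.linspace(0.05, 0.15, 10), np.linspace(0.3, 0.4, 10)])
        out = np.array([1] * 10 + [0] * 10)
        roc = ss.roc_cutoff(idx, out)
        assert roc.auc == pytest.approx(1.0)
        assert roc.sensitivity == pytest.approx(1.0)
        assert roc.specificity == pytest.approx(1.0)
        assert roc.direction == "low"
        assert 0.15 <= roc.cutoff < 0.3

    def test_independent_outcome_auc_near_half(self, rng):
        idx = rng.uniform(0, 1, 2_000)
        out = rng.integers(0, 2, 2_000)
        roc = ss.roc_cutoff(idx, out)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_all_pairs_concordance(self, rng):
        """12-vs-12 sample: AUC must equal the brute-force fraction of
        concordant (healthy above impaired) pairs, ties counted half."""
        impaired = rng.normal(0.15, 0.07, 12)
        healthy = rng.normal(0.30, 0.09, 12)
        idx = np.concatenate([impaired, healthy])
        out = np.array([1] * 12 + [0] * 12)
        roc = ss.roc_cutoff(idx, out)
        oracle = np.mean([
            1.0 if h > i else (0.5 if h == i else 0.0)
            for h in healthy for i in impaired
        ])
        assert roc.auc == pytest.approx(oracle, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        idx = r.uniform(0.01, 0.99, 30)
        out = r.integers(0, 2, 30)
        if out.min() == out.max():
            return
        base = ss.roc_cutoff(idx, out)
        warped = ss.roc_cutoff(np.log(idx) + idx ** 3, out)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError, match="classes"):
            ss.roc_cutoff([0.1, 0.2], [1, 1])


class TestSampleSize:
    def test_reference_design_needs_20_participants(self):
        """Delta 0.08, SD 0.06, alpha 0.05, power 0.80 -> 20 in total."""
        assert ss.sample_size(ss.PowerSpec()) == 20

    def test_matches_independent_power_solver(self):
        """statsmodels' t-test power solver agrees on the per-group n."""
        from statsmodels.stats.power import TTestIndPower

        spec = ss.PowerSpec()
        n = TTestIndPower().solve_power(
            effect_size=spec.min_difference / spec.sd, alpha=spec.alpha,
            power=spec.power, alternative="two-sided",
        )
        assert ss.sample_size(spec) == 2 * int(np.ceil(n))

    def test_doubling_difference_shrinks_n(self):
        base = ss.sample_size(ss.PowerSpec())
        halved = ss.sample_size(ss.PowerSpec(min_difference=0.16))
        assert halved < base

    def test_monte_carlo_power_at_returned_n(self, rng):
        """Simulated power at the returned n reaches the target (10 000 trials)."""
        spec = ss.PowerSpec()
        n = ss.sample_size(spec) // 2
        reps = 10_000
        a = rng.normal(0.0, spec.sd, (reps, n))
        b = rng.normal(spec.min_difference, spec.sd, (reps, n))
        from scipy import stats as sps
        t, p = sps.ttest_ind(a, b, axis=1)
        power = np.mean(p < spec.alpha)
        assert power >= spec.power - 3 * np.sqrt(spec.power * (1 - spec.power) / reps)

    def test_zero_difference_rejected(self):
        with pytest.raises(StatsError):
            ss.PowerSpec(min_difference=0.0)
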