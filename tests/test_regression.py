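"""Weighted regression, BIC selection, piecewise search, slope comparison."""

import numpy as np
import pandas as pd
import pytest

from trbdyn.regression import (
    ModelSpec,
    bic_backward_select,
    compare_slopes,
    enumerate_submodels,
    piecewise_search,
    weighted_fit,
)
from trbdyn.synthetic import CohortParams, StatusLaw, simulate_cohort


def toy_frame(age, y, weights=None, sex=None):
    n = len(age)
    return pd.DataFrame(
        {
            "age": age,
            "status_J": y,
            "sex": sex if sex is not None else ["male"] * n,
            "N": weights if weights is not None else np.ones(n),
        }
    )


class TestWeightedFit:
    def test_exact_linear_data_interpolated(self, rng):
        age = np.arange(10, 60, 5)
        y = 0.9 - 0.001 * age
        data = toy_frame(age, y, weights=rng.uniform(1, 100, len(age)))
        fit = weighted_fit(data, ModelSpec(terms=("AGE",)))
        assert fit.params["AGE"] == pytest.approx(-0.001, abs=1e-12)
        assert fit.params["Intercept"] == pytest.approx(0.9, abs=1e-12)
        assert fit.rss_w == pytest.approx(0.0, abs=1e-20)

    def test_equal_weights_match_statsmodels_ols(self):
        """Independent oracle: statsmodels on the same 5-point toy set."""
        import statsmodels.api as sm

        age = np.array([1.0, 2, 3, 5, 8])
        y = np.array([0.2, 0.25, 0.2, 0.35, 0.5])
        data = toy_frame(age, y)
        fit = weighted_fit(data, ModelSpec(terms=("AGE",)))
        X = sm.add_constant(age)
        ols = sm.OLS(y, X).fit()
        assert fit.params["Intercept"] == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.params["AGE"] == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.bse["AGE"] == pytest.approx(ols.bse[1], abs=1e-10)
        assert fit.f_pvalue == pytest.approx(ols.f_pvalue, abs=1e-10)

    def test_matches_statsmodels_wls_with_weights(self, rng):
        import statsmodels.api as sm

        n = 40
        age = rng.uniform(1, 74, n)
        female = rng.random(n) < 0.5
        y = 0.6 - 0.002 * age + 0.01 * female + rng.normal(0, 0.02, n)
        w = rng.uniform(1, 50, n)
        data = toy_frame(age, y, weights=w, sex=np.where(female, "female", "male"))
        fit = weighted_fit(data, ModelSpec())
        X = np.column_stack([np.ones(n), age, female, age * female])
        wls = sm.WLS(y, X, weights=w / w.mean()).fit()
        for i, term in enumerate(["Intercept", "AGE", "SEX", "AGE:SEX"]):
            assert fit.params[term] == pytest.approx(wls.params[i], abs=1e-10)
            assert fit.bse[term] == pytest.approx(wls.bse[i], abs=1e-10)
        assert fit.llf == pytest.approx(wls.llf, abs=1e-8)

    def test_weight_splitting_equivalence(self):
        """One sample at weight w equals two copies at w/2 each."""
        age = np.array([1.0, 2, 3, 5, 8])
        y = np.array([0.2, 0.25, 0.2, 0.35, 0.5])
        w = np.array([4.0, 2, 2, 6, 1])
        single = weighted_fit(toy_frame(age, y, w), ModelSpec(terms=("AGE",)))
        age2 = np.concatenate([age, age])
        y2 = np.concatenate([y, y])
        w2 = np.concatenate([w / 2, w / 2])
        double = weighted_fit(toy_frame(age2, y2, w2), ModelSpec(terms=("AGE",)))
        assert single.params["AGE"] == pytest.approx(double.params["AGE"], abs=1e-12)
        assert single.params["Intercept"] == pytest.approx(
            double.params["Intercept"], abs=1e-12
        )

    def test_single_sex_subset_raises_naming_sex(self):
        data = toy_frame(np.arange(10.0), np.linspace(0.5, 0.6, 10))
        with pytest.raises(ValueError, match="singular"):
            weighted_fit(data, ModelSpec(terms=("AGE", "SEX")))

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(terms=("AGE:SEX",))


class TestBICSelection:
    def _cohort(self, seed, status):
        params = CohortParams(
            n_donors=200, n_clones=1000, depth_range=(20_000, 80_000), status=status
        )
        table, _ = simulate_cohort(params, seed=seed)
        return table

    def test_strong_age_effect_selects_age(self):
        status = StatusLaw(
            intercept_young=0.70, slope_young=-0.004, breakpoint=None
        )
        table = self._cohort(11, status)
        spec, _ = bic_backward_select(table, ModelSpec())
        assert "AGE" in spec.terms
        assert "AGE:SEX" not in spec.terms

    def test_pure_noise_selects_intercept_only(self):
        status = StatusLaw(intercept_young=0.63, slope_young=0.0, breakpoint=None)
        table = self._cohort(12, status)
        spec, _ = bic_backward_select(table, ModelSpec())
        assert spec.terms == ()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_result_is_global_bic_minimum(self, seed):
        """Exhaustive oracle over all hierarchical submodels."""
        rng = np.random.default_rng(seed)
        n = 60
        age = rng.uniform(1, 74, n)
        female = rng.random(n) < 0.5
        y = 0.6 - 0.001 * age + 0.02 * female + rng.normal(0, 0.03, n)
        data = toy_frame(age, y, weights=rng.uniform(1, 10, n),
                         sex=np.where(female, "female", "male"))
        full = ModelSpec()
        spec, fit = bic_backward_select(data, full)
        best = min(
            (weighted_fit(data, s).bic, i) for i, s in enumerate(enumerate_submodels(full))
        )
        assert fit.bic == pytest.approx(best[0], abs=1e-9)


class TestPiecewise:
    def test_min_group_honoured(self, rng):
        age = np.concatenate([[1, 1, 1, 1], np.arange(30, 60)])
        y = rng.normal(0.6, 0.01, len(age))
        data = toy_frame(age, y)
        pw = piecewise_search(data, ModelSpec(terms=("AGE",)), min_group=5)
        assert pw.n_younger >= 5 and pw.n_older >= 5
        assert pw.split_age != 1  # split at 1 would leave 4 on the young side

    def test_no_feasible_split_raises(self, rng):
        data = toy_frame(np.array([30] * 6), rng.normal(0.6, 0.01, 6))
        with pytest.raises(ValueError, match="no feasible split"):
            piecewise_search(data, ModelSpec(terms=("AGE",)))

    def test_argmin_equals_exhaustive_oracle_single_slope(self, rng):
        """On single-slope data the BIC-sum surface is flat within noise;
        the only contract is argmin identity with an exhaustive scan."""
        age = rng.integers(1, 75, 150)
        y = 0.65 - 0.0005 * age + rng.normal(0, 0.02, 150)
        data = toy_frame(age, y, weights=rng.uniform(1, 20, 150))
        full = ModelSpec(terms=("AGE",))
        pw = piecewise_search(data, full, min_group=5)
        # independent scan using the public selection function
        best = None
        for a in np.unique(age)[:-1]:
            young, old = data[data.age <= a], data[data.age > a]
            if len(young) < 5 or len(old) < 5:
                continue
            s = bic_backward_select(young, full)[1].bic + bic_backward_select(old, full)[1].bic
            if best is None or s < best[0]:
                best = (s, int(a))
        assert pw.split_age == best[1]
        assert pw.bic_sum == pytest.approx(best[0], abs=1e-9)

    def test_recovers_embedded_breakpoint(self):
        """Default two-segment status law: split 18 found at cohort scale."""
        params = CohortParams(n_donors=480, n_clones=2000, depth_range=(50_000, 200_000))
        table, _ = simulate_cohort(params, seed=77)
        pw = piecewise_search(table, ModelSpec(response="status_J"), min_group=5)
        assert abs(pw.split_age - 18) <= 1
        assert pw.younger.params["AGE"] == pytest.approx(-0.006, abs=0.002)


class TestCompareSlopes:
    def test_identical_fits_give_p_one(self, rng):
        age = np.arange(1, 40.0)
        y = 0.6 - 0.001 * age + rng.normal(0, 0.01, len(age))
        data = toy_frame(age, y)
        fit = weighted_fit(data, ModelSpec(terms=("AGE",)))
        t, p = compare_slopes(fit, fit)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_slopes_tiny_p(self, rng):
        age = np.arange(1, 60.0)
        a = weighted_fit(
            toy_frame(age, -0.005 * age + rng.normal(0, 0.005, len(age))),
            ModelSpec(terms=("AGE",)),
        )
        b = weighted_fit(
            toy_frame(age, 0.005 * age + rng.normal(0, 0.005, len(age))),
            ModelSpec(terms=("AGE",)),
        )
        _, p = compare_slopes(a, b)
        assert p < 1e-6

    def test_requires_age_term(self, rng):
        age = np.arange(1, 30.0)
        data = toy_frame(age, rng.normal(0.6, 0.01, len(age)))
        with_age = weighted_fit(data, ModelSpec(terms=("AGE",)))
        without = weighted_fit(data, ModelSpec(terms=()))
        with pytest.raises(ValueError, match="AGE"):
            compare_slopes(with_age, without)

    def test_null_calibration_uniform_p(self):
        """Equal true slopes: p-values approximately uniform (KS check)."""
        from scipy import stats

        rng = np.random.default_rng(5)
        pvals = []
        age = np.arange(1, 41.0)
        for _ in range(300):
            ya = 0.6 - 0.001 * age + rng.normal(0, 0.02, len(age))
            yb = 0.6 - 0.001 * age + rng.normal(0, 0.02, len(age))
            a = weighted_fit(toy_frame(age, ya), ModelSpec(terms=("AGE",)))
            b = weighted_fit(toy_frame(age, yb), ModelSpec(terms=("AGE",)))
            pvals.append(compare_slopes(a, b)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
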