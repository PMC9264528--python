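"""Evaluation statistics: percent bias, regressions, Cronbach's alpha,
bias t-tests, leave-one-out evaluation and grid bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from lfqimpute import (GridConfig, MissingnessSpec, SampleMetadata,
                       SIMethodParams, SyntheticConfig, ValidationError,
                       bias_ttest, compare_regressions, cronbach_alpha,
                       fraction_correct, generate_structured_dataset,
                       loo_structural_eval, percent_bias, percent_bias_array,
                       regress_covariate, run_experiment_grid)

from conftest import make_matrix


class TestPercentBias:
    @pytest.mark.parametrize("imputed,true,expected",
                             [(21.0, 20.0, 5.0), (19.0, 20.0, 5.0),
                              (7.3, 7.3, 0.0)])
    def test_known_values(self, imputed, true, expected):
        assert percent_bias(imputed, true) == pytest.approx(expected)

    def test_zero_truth_flagged_infinite(self):
        assert math.isinf(percent_bias(1.0, 0.0))

    @given(st.floats(-1e6, 1e6), st.floats(0.01, 1e6), st.floats(0.01, 1e3))
    def test_scale_invariance(self, imputed, true, c):
        assert percent_bias(c * imputed, c * true) == \
            pytest.approx(percent_bias(imputed, true), rel=1e-9)

    def test_array_form_matches_scalar(self, rng):
        imp = rng.normal(size=20)
        true = rng.normal(size=20) + 3
        arr = percent_bias_array(imp, true)
        for k in range(20):
            assert arr[k] == pytest.approx(percent_bias(imp[k], true[k]))


class TestFractionCorrect:
    def test_strict_inequality_at_threshold(self):
        assert fraction_correct([4.9, 5.0, 5.1]) == pytest.approx(1 / 3)

    def test_all_zero(self):
        assert fraction_correct([0.0, 0.0]) == 1.0

    def test_infinite_threshold(self):
        assert fraction_correct([1e9, 2.0], threshold=math.inf) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fraction_correct([])


class TestRegression:
    def meta(self, ages):
        return SampleMetadata([f"S{j}" for j in range(len(ages))],
                              np.asarray(ages, float))

    def test_exact_line(self):
        m = make_matrix([[2.0, 4.0, 6.0]])
        fit = regress_covariate(m, self.meta([1, 2, 3]))
        assert fit["beta"].iloc[0] == pytest.approx(2.0)
        assert fit["se"].iloc[0] == pytest.approx(0.0)

    def test_three_point_closed_form(self):
        m = make_matrix([[1.0, 2.0, 2.0]])
        fit = regress_covariate(m, self.meta([1, 2, 3]))
        assert fit["beta"].iloc[0] == pytest.approx(0.5)

    def test_constant_protein(self):
        m = make_matrix([[3.0, 3.0, 3.0, 3.0]])
        fit = regress_covariate(m, self.meta([1, 2, 3, 4]))
        assert fit["beta"].iloc[0] == pytest.approx(0.0)

    def test_agrees_with_statsmodels(self, rng):
        vals = rng.normal(20, 1, size=(20, 12))
        ages = rng.uniform(7, 23, size=12)
        fits = regress_covariate(make_matrix(vals), self.meta(ages))
        design = sm.add_constant(ages)
        for i in range(20):
            ref = sm.OLS(vals[i], design).fit()
            assert fits["beta"].iloc[i] == pytest.approx(ref.params[1], abs=1e-10)
            assert fits["se"].iloc[i] == pytest.approx(ref.bse[1], abs=1e-10)
            assert fits["p"].iloc[i] == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_zero_age_variance_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError, match="age variance"):
            regress_covariate(m, self.meta([5, 5, 5]))

    def test_incomplete_matrix_rejected(self):
        m = make_matrix([[1.0, np.nan, 3.0]])
        with pytest.raises(ValidationError, match="complete"):
            regress_covariate(m, self.meta([1, 2, 3]))

    def test_identical_fits_give_zero_deltas(self, rng):
        vals = rng.normal(20, 1, size=(5, 10))
        fits = regress_covariate(make_matrix(vals),
                                 self.meta(rng.uniform(7, 23, 10)))
        deltas = compare_regressions(fits, fits)
        assert (deltas["delta_beta"] == 0).all()
        assert (deltas["delta_p"] == 0).all()


class TestCronbachAlpha:
    def test_two_item_closed_form(self, rng):
        # construct data whose sample covariance is exactly [[1,.5],[.5,1]]:
        # alpha = 2 * (1 - 2/3) = 2/3
        z = rng.normal(size=(2, 50))
        z -= z.mean(axis=1, keepdims=True)
        cov = np.cov(z)
        z = np.linalg.inv(np.linalg.cholesky(cov)) @ z       # whiten exactly
        target = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        data = target @ z
        assert cronbach_alpha(data) == pytest.approx(2 / 3, abs=1e-10)

    def test_identical_items(self):
        row = np.array([1.0, 2.0, 5.0, 3.0])
        assert cronbach_alpha(np.vstack([row, row])) == pytest.approx(1.0)

    def test_brute_force_covariance_oracle(self, rng):
        for _ in range(20):
            data = rng.normal(size=(5, 20))
            cov = np.cov(data)
            brute = 5 / 4 * (1 - np.trace(cov) / cov.sum())
            assert cronbach_alpha(data) == pytest.approx(brute, abs=1e-10)

    def test_independent_items_near_zero(self, rng):
        alphas = [cronbach_alpha(rng.normal(size=(2, 200))) for _ in range(200)]
        assert abs(np.mean(alphas)) < 0.1

    def test_validation(self):
        with pytest.raises(ValidationError):
            cronbach_alpha(np.ones((1, 5)))
        with pytest.raises(ValidationError):
            cronbach_alpha(np.ones((3, 5)))  # zero total variance


class TestBiasTTest:
    def test_all_zero_not_significant(self):
        res = bias_ttest([0.0] * 10)
        assert res.p == 1.0 and not res.significant_05

    def test_clear_shift_significant(self, rng):
        res = bias_ttest(1.0 + 1e-6 * rng.normal(size=20))
        assert res.p < 1e-6 and res.significant_001

    def test_bonferroni_scales_p(self, rng):
        d = rng.normal(0.5, 1.0, size=30)
        res1 = bias_ttest(d, n_tests=1)
        res10 = bias_ttest(d, n_tests=10)
        assert res10.p_bonferroni == pytest.approx(min(1.0, res1.p * 10))

    def test_type_one_error_calibrated(self, rng):
        rejections = sum(bias_ttest(rng.normal(size=20)).p < 0.05
                         for _ in range(500))
        assert 0.02 < rejections / 500 < 0.09


class TestLeaveOneOut:
    def make_dataset(self):
        cfg = SyntheticConfig(n_proteins=20, n_samples=12, seed=5,
                              block_sizes=(10, 10))
        return generate_structured_dataset(cfg, MissingnessSpec("MIX", 0.1,
                                                                seed=2))

    def test_single_iteration_mean_imputation_closed_form(self):
        ds = self.make_dataset()
        rng = np.random.default_rng(0)
        rec = loo_structural_eval(ds, SIMethodParams(method="mean"),
                                  n_iter=1, rng=rng)
        row = rec.iloc[0]
        i = ds.observed.protein_ids.index(row["protein"])
        j = ds.observed.sample_ids.index(row["sample"])
        others = np.delete(ds.observed.values[i], j)
        expected = np.nanmean(others)
        assert row["imputed_value"] == pytest.approx(expected)
        assert row["percent_bias"] == pytest.approx(
            100 * abs(expected - row["true_value"]) / abs(row["true_value"]))

    def test_matrix_restored_after_run(self):
        ds = self.make_dataset()
        before = ds.observed.values.copy()
        loo_structural_eval(ds, SIMethodParams(method="mean"), n_iter=10,
                            rng=np.random.default_rng(1))
        np.testing.assert_array_equal(ds.observed.values, before)

    def test_iteration_budget_checked(self):
        ds = self.make_dataset()
        with pytest.raises(ValidationError, match="exceeds"):
            loo_structural_eval(ds, SIMethodParams(method="mean"),
                                n_iter=10 ** 6)


class TestExperimentGrid:
    def small_grid(self, **overrides):
        base = dict(
            experiment="accuracy_screen", mechanisms=("MCAR",), rates=(0.1,),
            methods=("zero", "mean"), n_proteins=(10,), n_iterations=2,
            master_seed=3,
            synthetic=SyntheticConfig(n_proteins=30, n_samples=20, seed=1))
        base.update(overrides)
        return GridConfig(**base)

    def test_bookkeeping_rows_and_seeds(self):
        table = run_experiment_grid(self.small_grid())
        # 2 methods x 1 rate x 2 iterations x 2 statistics
        assert len(table) == 8
        assert table["status"].eq("ok").all()
        assert table.groupby("iteration")["seed"].nunique().eq(1).all()
        assert table[table.iteration == 0]["seed"].iloc[0] != \
            table[table.iteration == 1]["seed"].iloc[0]

    def test_rerun_is_byte_identical(self):
        a = run_experiment_grid(self.small_grid())
        b = run_experiment_grid(self.small_grid())
        pd.testing.assert_frame_equal(a, b)

    def test_mi_failure_recorded_not_silent(self):
        grid = self.small_grid(
            experiment="regression_bias", methods=("mice_norm",),
            n_proteins=(25,), n_iterations=1, rates=(0.2,),
            synthetic=SyntheticConfig(n_proteins=30, n_samples=20, seed=1))
        table = run_experiment_grid(grid)
        assert len(table) == 1
        assert table["status"].iloc[0] == "failed: singular"
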