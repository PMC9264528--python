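"""Single-imputation registry: exactness limits, degenerate cases,
pass-through of observed cells, determinism."""

import numpy as np
import pytest

from lfqimpute import (ImputationFailure, MissingnessSpec, SIMethodParams,
                       ValidationError, impute, impute_with_provenance, inject)
from lfqimpute.impute_si import SI_METHODS, _median_fill

from conftest import make_matrix


def masked_cohort(small_cohort, rate=0.15, seed=3):
    complete, _ = small_cohort
    return complete, inject(complete, MissingnessSpec("MIX", rate, seed=seed))


class TestConstantFills:
    def test_zero_fill(self):
        m = make_matrix([[np.nan, 1.0], [2.0, np.nan]])
        out = impute(m, SIMethodParams(method="zero"))
        assert out.values[0, 0] == 0.0 and out.values[1, 1] == 0.0

    def test_mean_fill(self):
        m = make_matrix([[2.0, np.nan, 4.0]])
        out = impute(m, SIMethodParams(method="mean"))
        assert out.values[0, 1] == 3.0

    def test_median_initial_fill(self):
        filled = _median_fill(np.array([[1.0, np.nan, 3.0]]))
        assert filled[0, 1] == 2.0


@pytest.mark.parametrize("method", SI_METHODS)
class TestRegistryContracts:
    def test_identity_on_complete(self, method, rng):
        m = make_matrix(rng.normal(20, 1, size=(12, 8)))
        res = impute_with_provenance(m, SIMethodParams(method=method, max_iter=2))
        assert res.matrix == m
        assert res.n_iter == 0

    def test_observed_cells_bit_exact(self, method, small_cohort):
        complete, injection = masked_cohort(small_cohort)
        masked = injection.masked_matrix
        params = SIMethodParams(method=method, max_iter=3, n_trees=10)
        out = impute(masked, params)
        obs = masked.mask
        assert np.array_equal(out.values[obs], masked.values[obs])
        assert np.isfinite(out.values).all()

    def test_deterministic_given_params(self, method, small_cohort):
        complete, injection = masked_cohort(small_cohort)
        params = SIMethodParams(method=method, max_iter=2, n_trees=10, seed=5)
        a = impute(injection.masked_matrix, params)
        b = impute(injection.masked_matrix, params)
        assert a == b


class TestFailureModes:
    def test_unknown_method(self):
        with pytest.raises(ValidationError, match="unknown"):
            SIMethodParams(method="magic")

    def test_all_missing_protein(self):
        m = make_matrix([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ImputationFailure, match="zero observed"):
            impute(m, SIMethodParams(method="mean"))

    def test_seqknn_needs_complete_seed(self):
        vals = np.array([[1.0, np.nan, 3.0], [np.nan, 2.0, 3.0],
                         [1.0, 2.0, np.nan]])
        with pytest.raises(ImputationFailure, match="seqknn"):
            impute(make_matrix(vals), SIMethodParams(method="seqknn"))

    def test_rf_seed_changes_output(self, small_cohort):
        complete, injection = masked_cohort(small_cohort)
        a = impute(injection.masked_matrix,
                   SIMethodParams(method="rf", n_trees=10, max_iter=1, seed=1))
        b = impute(injection.masked_matrix,
                   SIMethodParams(method="rf", n_trees=10, max_iter=1, seed=2))
        assert not np.array_equal(a.values, b.values)


class TestLocalRegression:
    def test_duplicated_row_is_perfect_predictor(self, rng):
        base = rng.normal(20, 1, size=10)
        vals = np.vstack([base, base, rng.normal(20, 1, size=10)])
        vals[0, 4] = np.nan
        out = impute(make_matrix(vals), SIMethodParams(method="lls", k_neighbors=1))
        assert out.values[0, 4] == pytest.approx(base[4], abs=1e-8)

    def test_proportional_neighbor_halved(self, rng):
        target = rng.normal(20, 1, size=12)
        vals = np.vstack([target, 2.0 * target])
        vals[0, 3] = np.nan
        out = impute(make_matrix(vals), SIMethodParams(method="lls", k_neighbors=1))
        assert out.values[0, 3] == pytest.approx(2.0 * target[3] / 2.0, abs=1e-8)

    def test_grr_matches_lls_as_penalty_vanishes(self, small_cohort):
        complete, injection = masked_cohort(small_cohort, rate=0.1)
        lls = impute(injection.masked_matrix, SIMethodParams(method="lls"))
        grr = impute(injection.masked_matrix,
                     SIMethodParams(method="grr", ridge_lambda=1e-10))
        miss = ~injection.masked_matrix.mask
        np.testing.assert_allclose(grr.values[miss], lls.values[miss],
                                   rtol=1e-4, atol=1e-4)

    def test_grr_shrinks_to_mean_at_huge_penalty(self, rng):
        vals = rng.normal(20, 1, size=(6, 12))
        vals[0, 0] = np.nan
        m = make_matrix(vals)
        out = impute(m, SIMethodParams(method="grr", ridge_lambda=1e12))
        target_mean = np.nanmean(vals[0])
        assert out.values[0, 0] == pytest.approx(target_mean, abs=1e-4)

    def test_grr_survives_collinear_neighbors(self, rng):
        base = rng.normal(20, 1, size=10)
        vals = np.vstack([base + rng.normal(0, 0.05, 10), base, base, base])
        vals[0, 2] = np.nan
        out = impute(make_matrix(vals), SIMethodParams(method="grr"))
        assert np.isfinite(out.values[0, 2])
        assert abs(out.values[0, 2] - base[2]) < 1.0


class TestGlobalStructure:
    def test_bpca_completes_noiseless_rank_one(self, rng):
        a = rng.uniform(1, 2, size=12)
        b = rng.uniform(10, 20, size=8)
        vals = np.outer(a, b)
        vals[3, 5] = np.nan
        out = impute(make_matrix(vals),
                     SIMethodParams(method="bpca", rank=1, max_iter=500,
                                    tol=1e-9))
        value_range = np.ptp(np.outer(a, b))
        err = abs(out.values[3, 5] - a[3] * b[5]) / value_range
        assert err < 1e-6

    def test_bpca_on_pure_noise_stays_near_protein_mean(self, rng):
        vals = rng.normal(20, 1, size=(40, 20))
        vals[0, 0] = np.nan
        out = impute(make_matrix(vals),
                     SIMethodParams(method="bpca", max_iter=100, tol=1e-6))
        # no structure: ARD kills the factors, reconstruction ~ the mean
        assert abs(out.values[0, 0] - np.nanmean(vals[0])) < 1.0

    def test_svd_full_rank_reproduces_mean_fill(self, rng):
        vals = rng.normal(20, 1, size=(6, 4))
        vals[1, 2] = np.nan
        m = make_matrix(vals)
        res = impute_with_provenance(m, SIMethodParams(method="svd", rank=4))
        mean_filled = impute(m, SIMethodParams(method="mean"))
        np.testing.assert_allclose(res.matrix.values, mean_filled.values,
                                   atol=1e-10)
        assert res.n_iter == 1

    def test_svd_completes_noiseless_rank_one(self, rng):
        a = rng.uniform(1, 2, size=12)
        b = rng.uniform(10, 20, size=8)
        vals = np.outer(a, b)
        vals[3, 5] = np.nan
        out = impute(make_matrix(vals),
                     SIMethodParams(method="svd", rank=1, max_iter=500, tol=1e-12))
        err = abs(out.values[3, 5] - a[3] * b[5]) / np.ptp(np.outer(a, b))
        assert err < 1e-6


class TestNeighborAveraging:
    def test_knn_with_all_neighbors_is_mean_of_others(self, rng):
        vals = rng.normal(20, 1, size=(6, 5))
        vals[0, 2] = np.nan
        out = impute(make_matrix(vals),
                     SIMethodParams(method="knn", k_neighbors=5))
        assert out.values[0, 2] == pytest.approx(vals[1:, 2].mean())

    def test_seqknn_single_incomplete_matches_knn(self, rng):
        vals = rng.normal(20, 1, size=(8, 6))
        vals[2, 1] = np.nan
        params_knn = SIMethodParams(method="knn", k_neighbors=3)
        params_seq = SIMethodParams(method="seqknn", k_neighbors=3)
        m = make_matrix(vals)
        np.testing.assert_allclose(impute(m, params_knn).values,
                                   impute(m, params_seq).values)


class TestRandomForest:
    def test_rank_one_structure_recovered(self, rng):
        # noiseless rank-1 with 10% MCAR: monotone relation between proteins,
        # forest interpolation should land within 5% bias for most cells
        a = rng.uniform(1, 2, size=30)
        b = rng.uniform(10, 20, size=40)
        truth = np.outer(a, b)
        m = make_matrix(truth)
        injection = inject(m, MissingnessSpec("MCAR", 0.1, seed=4))
        out = impute(injection.masked_matrix,
                     SIMethodParams(method="rf", n_trees=50, max_iter=5, seed=0))
        imp = np.array([out.values[i, j] for i, j in injection.cells()])
        true = injection.truth_values()
        bias = 100 * np.abs(imp - true) / np.abs(true)
        assert (bias < 5.0).mean() > 0.95
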