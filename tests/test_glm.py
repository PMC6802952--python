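"""RDM vectorization, OLS modelling, residualization and the analysis suite."""

import numpy as np
import pytest

from schemarsa import (
    CollinearPredictorsError,
    GroundTruth,
    RDMRegression,
    Residualizer,
    build_category_rdm,
    build_cross_type_mask,
    build_location_rdm,
    build_stimulus_set,
    dataset_rdms,
    fit_rdm_glm,
    residualize,
    run_glm_suite,
    simulate_fmri,
    vectorize,
)
from schemarsa.design import default_predictor_rdms
from schemarsa.glm import zscore

from oracles import ols_betas_oracle, residualize_oracle


def _symmetric_from_vector(vec, n):
    values = np.full((n, n), np.nan)
    tri = np.tril_indices(n, -1)
    values[tri] = vec
    values[tri[1], tri[0]] = vec
    return values


class TestVectorize:
    def test_pair_counts(self, default_set):
        rdm = build_location_rdm(default_set, "vertical")
        assert vectorize(rdm).n_pairs == 630
        mask = build_cross_type_mask(default_set)
        assert vectorize(rdm, mask).n_pairs == 324
        two = build_stimulus_set(1, 1, 1)
        assert vectorize(build_category_rdm(two)).n_pairs == 1

    def test_canonical_order_is_row_major_lower_triangle(self, default_set):
        vec = vectorize(build_location_rdm(default_set, "vertical"))
        tri = np.tril_indices(36, -1)
        assert np.array_equal(vec.rows, tri[0])
        assert np.array_equal(vec.cols, tri[1])

    def test_size_mismatch_rejected(self, default_set):
        mask = build_cross_type_mask(default_set)
        with pytest.raises(ValueError, match="does not match"):
            vectorize(np.zeros((8, 8)), mask)


class TestFit:
    def test_recovers_planted_weights_against_normal_equations(self, default_set):
        preds = default_predictor_rdms(default_set)
        v = vectorize(preds["vertical"]).values
        h = vectorize(preds["horizontal"]).values
        c = vectorize(preds["category"]).values
        y = 2.0 * v + 1.0 * c
        res = fit_rdm_glm(y, {"vertical": v, "horizontal": h, "category": c})
        assert res.betas["vertical"] / res.betas["category"] == pytest.approx(2.0, abs=1e-10)
        assert res.betas["horizontal"] == pytest.approx(0.0, abs=1e-10)
        want = ols_betas_oracle(np.column_stack([v, h, c]), zscore(y))
        got = [res.betas["vertical"], res.betas["horizontal"], res.betas["category"]]
        assert np.allclose(got, want[1:], atol=1e-10)
        assert res.intercept == pytest.approx(want[0], abs=1e-10)

    def test_criterion_equal_to_one_predictor(self, default_set):
        v = vectorize(build_location_rdm(default_set, "vertical")).values
        h = vectorize(build_location_rdm(default_set, "horizontal")).values
        res = fit_rdm_glm(v, {"vertical": v, "horizontal": h})
        assert res.betas["vertical"] > 0
        assert res.betas["horizontal"] == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_criterion_warns_and_zeroes(self, default_set):
        v = vectorize(build_location_rdm(default_set, "vertical")).values
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = fit_rdm_glm(np.full_like(v, 3.0), {"vertical": v})
        assert res.betas["vertical"] == 0.0

    def test_collinear_predictors_error_names_columns(self, default_set):
        v = vectorize(build_location_rdm(default_set, "vertical")).values
        with pytest.raises(CollinearPredictorsError, match="vertical"):
            fit_rdm_glm(v + 0.5, {"vertical": v, "vertical_copy": v.copy()})

    def test_zscoring_rescales_betas_by_common_positive_factor(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, -0.5, 2.0] + rng.normal(size=40)
        raw = RDMRegression(zscore_criterion=False).fit(X, y).coef_
        scaled = RDMRegression(zscore_criterion=True).fit(X, y).coef_
        ratio = scaled / raw
        assert ratio.std() < 1e-10 and ratio[0] > 0

    def test_frisch_waugh_consistency(self, rng):
        """Joint beta equals the beta of doubly-residualized simple regression."""
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        joint = RDMRegression(zscore_criterion=False).fit(X, y).coef_[0]
        others = X[:, 1:]
        y_res = residualize(y, [others[:, 0], others[:, 1]])
        x_res = residualize(X[:, 0], [others[:, 0], others[:, 1]])
        simple = RDMRegression(zscore_criterion=False).fit(x_res[:, None], y_res).coef_[0]
        assert joint == pytest.approx(simple, abs=1e-10)


class TestResidualize:
    def test_covariate_containing_structure_annihilates_it(self, default_set):
        c = vectorize(build_category_rdm(default_set)).values
        y = 1.4 * c + 0.3
        resid = residualize(y, [c])
        simple = RDMRegression(zscore_criterion=False).fit(c[:, None], resid).coef_[0]
        assert simple == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_covariates_leave_centered_criterion(self, rng):
        cov = rng.normal(size=30)
        covc = cov - cov.mean()
        y = rng.normal(size=30)
        y = y - y.mean()
        y = y - (y @ covc) / (covc @ covc) * covc  # orthogonal to the covariate
        resid = residualize(y + 7.0, [cov])  # the intercept removes the offset
        assert np.allclose(resid, y, atol=1e-10)

    def test_matches_two_step_ols_oracle(self, rng):
        y = rng.normal(size=25)
        C = rng.normal(size=(25, 3))
        got = residualize(y, [C[:, 0], C[:, 1], C[:, 2]])
        assert np.allclose(got, residualize_oracle(y, C), atol=1e-10)

    def test_residualizer_transformer_contract(self, rng):
        C = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 4))
        out = Residualizer().fit(C).transform(Y)
        assert out.shape == Y.shape
        for k in range(4):
            assert np.allclose(out[:, k], residualize_oracle(Y[:, k], C), atol=1e-10)


class TestRunGlmSuite:
    def test_planted_vertical_effect_recovered_across_subjects(self, default_set):
        truth = GroundTruth(weights={"vertical": 1.0}, unique_weight=0.5, noise_scale=3.0)
        ds = simulate_fmri(default_set, n_subjects=5, n_voxels=60, n_runs=6,
                           truth=truth, seed=42)
        res = run_glm_suite(dataset_rdms(ds), default_set, "full")
        assert res.betas.shape == (5, 1, 3)
        assert (res.predictor("vertical") > 0).all()
        assert abs(res.predictor("horizontal").mean()) < 0.1

    def test_cross_type_analysis_uses_324_pairs_and_keeps_vertical(self, default_set):
        truth = GroundTruth(weights={"vertical": 1.0}, unique_weight=0.5, noise_scale=3.0)
        ds = simulate_fmri(default_set, n_subjects=4, n_voxels=60, n_runs=6,
                           truth=truth, seed=43)
        res = run_glm_suite(dataset_rdms(ds), default_set, "cross_type")
        assert res.n_pairs == 324
        assert res.predictor_names == ["vertical", "horizontal"]
        assert (res.predictor("vertical") > 0).all()

    def test_category_under_cross_type_mask_is_an_error(self, default_set):
        preds = default_predictor_rdms(default_set)
        with pytest.raises(ValueError, match="category"):
            run_glm_suite(np.zeros((36, 36)), default_set, "cross_type",
                          predictors=preds)

    def test_bank_spanning_category_zeroes_its_beta_exactly(self, default_set):
        """Noise-free residualization control: category beta 0, vertical survives."""
        preds = default_predictor_rdms(default_set)
        v = vectorize(preds["vertical"]).values
        c = vectorize(preds["category"]).values
        neural = _symmetric_from_vector(0.9 * v + 0.6 * c, 36)
        bank = [preds["category"]]
        with pytest.warns(RuntimeWarning, match="covariate-bank span"):
            res = run_glm_suite(neural, default_set, "dnn_resid",
                                covariate_bank=bank, zscore_criterion=False)
        assert res.predictor("category")[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert res.predictor("vertical")[0, 0] == pytest.approx(0.9, abs=1e-10)

    def test_masked_betas_agree_in_sign_with_full_set(self, default_set):
        truth = GroundTruth(weights={"vertical": 1.0}, unique_weight=0.5,
                            noise_scale=2.0)
        ds = simulate_fmri(default_set, n_subjects=3, n_voxels=60, n_runs=6,
                           truth=truth, seed=44)
        rdms = dataset_rdms(ds)
        full = run_glm_suite(rdms, default_set, "full")
        masked = run_glm_suite(rdms, default_set, "cross_type")
        assert np.array_equal(np.sign(full.predictor("vertical")),
                              np.sign(masked.predictor("vertical")))
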