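"""Reconstruction engines: Tikhonov, columnwise EN, multitask group EN."""

import numpy as np
import pytest

import epiwave as ew
from epiwave.inverse import multitask_objective, lambda_max

from .oracles import (
    columns_group_elastic_net,
    elastic_net_objective,
    ridge_normal_equations,
    single_group_elastic_net,
    sklearn_columnwise_en,
    sklearn_multitask_en,
)


def _instance(seed, r=6, q=10, m=12):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(r, q)), rng.normal(size=(r, m))


class TestTikhonov:
    def test_identity_halves_at_unit_lambda(self):
        B = np.array([[1.0, 2.0], [3.0, 4.0]])
        res = ew.tikhonov_reconstruct(np.eye(2), B, lam=1.0)
        np.testing.assert_allclose(res.phi_h_hat.data, B / 2.0, atol=1e-12)

    def test_infinite_regularization_kills_solution(self):
        A, B = _instance(0)
        res = ew.tikhonov_reconstruct(A, B, lam=1e12)
        assert np.linalg.norm(res.phi_h_hat.data) < 1e-6 * np.linalg.norm(B)

    def test_matches_normal_equations(self):
        A, B = _instance(1, r=6, q=10)
        res = ew.tikhonov_reconstruct(A, B, lam=0.1)
        np.testing.assert_allclose(res.phi_h_hat.data,
                                   ridge_normal_equations(A, B, 0.1),
                                   atol=1e-8)

    def test_stationarity_residual(self):
        A, B = _instance(2)
        lam = 0.5
        P = ew.tikhonov_reconstruct(A, B, lam=lam).phi_h_hat.data
        resid = (A.T @ A + lam * np.eye(A.shape[1])) @ P - A.T @ B
        assert np.abs(resid).max() <= 1e-8 * np.abs(A.T @ B).max()

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ew.tikhonov_reconstruct(np.eye(2), np.eye(2), lam=-1.0)


class TestColumnwiseElasticNet:
    def test_ridge_limit_matches_tikhonov_half_lambda(self):
        A, B = _instance(3)
        lam = 2.0
        en = ew.elastic_net_columnwise(
            A, B, ew.RegularizationParams(lam=lam, alpha=0.0, tol=1e-15)
        )
        tik = ew.tikhonov_reconstruct(A, B, lam=lam / 2.0)
        diff = np.linalg.norm(en.phi_h_hat.data - tik.phi_h_hat.data)
        assert diff <= 1e-6 * np.linalg.norm(tik.phi_h_hat.data)

    def test_lasso_null_threshold(self):
        A, B = _instance(4)
        lam = 2.0 * np.abs(A.T @ B).max() + 1e-9
        res = ew.elastic_net_columnwise(
            A, B, ew.RegularizationParams(lam=lam, alpha=1.0)
        )
        assert np.abs(res.phi_h_hat.data).max() == 0.0

    @pytest.mark.parametrize("alpha", [0.5, 1.0])
    def test_objective_matches_sklearn(self, alpha):
        A, B = _instance(5, r=5, q=8, m=8)
        lam = 1.0
        ours = ew.elastic_net_columnwise(
            A, B, ew.RegularizationParams(lam=lam, alpha=alpha, tol=1e-12)
        ).phi_h_hat.data
        theirs = sklearn_columnwise_en(A, B, lam, alpha)
        f_ours = elastic_net_objective(A, ours, B, lam, alpha)
        f_or = elastic_net_objective(A, theirs, B, lam, alpha)
        assert f_ours <= f_or * (1 + 1e-6)
        assert f_or <= f_ours * (1 + 1e-6)

    def test_identity_design_soft_threshold(self):
        """With A = I and alpha = 1 each entry is soft-thresholded."""
        B = np.array([[3.0, -0.2], [-1.0, 0.9]])
        lam = 1.0
        res = ew.elastic_net_columnwise(
            np.eye(2), B, ew.RegularizationParams(lam=lam, alpha=1.0)
        )
        expected = np.sign(B) * np.maximum(np.abs(B) - lam / 2.0, 0.0)
        np.testing.assert_allclose(res.phi_h_hat.data, expected, atol=1e-10)


class TestMultiTaskGroupElasticNet:
    @pytest.mark.parametrize("grouping", ["node-rows", "coefficient-columns"])
    def test_ridge_limit(self, grouping):
        A, B = _instance(6)
        lam = 3.0
        est = ew.MultiTaskGroupElasticNet(lam=lam, alpha=0.0,
                                          grouping=grouping,
                                          tol=1e-15).fit(A, B)
        ridge = ridge_normal_equations(A, B, lam / 2.0)
        np.testing.assert_allclose(est.coef_full_, ridge, rtol=1e-6,
                                   atol=1e-9)

    @pytest.mark.parametrize("grouping", ["node-rows", "coefficient-columns"])
    def test_group_null_threshold_exact_zero(self, grouping):
        A, B = _instance(7)
        lam = lambda_max(A, B, alpha=1.0, grouping=grouping) * 1.0001
        est = ew.MultiTaskGroupElasticNet(lam=lam, alpha=1.0,
                                          grouping=grouping).fit(A, B)
        assert np.abs(est.coef_full_).max() == 0.0

    @pytest.mark.parametrize("alpha", [0.5, 0.9, 1.0])
    def test_node_rows_matches_sklearn_multitask(self, alpha):
        A, B = _instance(8, r=5, q=8, m=16)
        lam = 0.4 * lambda_max(A, B, alpha=alpha, grouping="node-rows")
        est = ew.MultiTaskGroupElasticNet(lam=lam, alpha=alpha,
                                          tol=1e-12, max_iter=50000).fit(A, B)
        theirs = sklearn_multitask_en(A, B, lam, alpha)
        f_ours = multitask_objective(A, est.coef_full_, B, lam, alpha)
        f_or = multitask_objective(A, theirs, B, lam, alpha)
        assert f_ours <= f_or * (1 + 1e-6)
        assert f_or <= f_ours * (1 + 1e-6)

    @pytest.mark.parametrize("alpha", [0.5, 0.9, 1.0])
    def test_columns_grouping_matches_closed_form(self, alpha):
        A, B = _instance(9, r=5, q=8, m=16)
        lam = 0.4 * lambda_max(A, B, alpha=alpha,
                               grouping="coefficient-columns")
        est = ew.MultiTaskGroupElasticNet(
            lam=lam, alpha=alpha, grouping="coefficient-columns",
            tol=1e-12, max_iter=50000,
        ).fit(A, B)
        theirs = columns_group_elastic_net(A, B, lam, alpha)
        f_ours = multitask_objective(A, est.coef_full_, B, lam, alpha,
                                     "coefficient-columns")
        f_or = multitask_objective(A, theirs, B, lam, alpha,
                                   "coefficient-columns")
        assert f_ours <= f_or * (1 + 1e-6)
        assert f_or <= f_ours * (1 + 1e-6)

    def test_identity_design_block_soft_threshold(self):
        """alpha=1, A=I, column groups: each column shrinks by the exact
        block soft-threshold formula."""
        rng = np.random.default_rng(10)
        B = rng.normal(size=(6, 5))
        lam = 1.2
        est = ew.MultiTaskGroupElasticNet(
            lam=lam, alpha=1.0, grouping="coefficient-columns", tol=1e-14,
            max_iter=50000,
        ).fit(np.eye(6), B)
        norms = np.linalg.norm(B, axis=0)
        expected = B * np.maximum(0.0, 1.0 - lam / (2.0 * norms))
        np.testing.assert_allclose(est.coef_full_, expected, atol=1e-8)

    def test_objective_trace_non_increasing(self):
        A, B = _instance(11)
        est = ew.MultiTaskGroupElasticNet(lam=1.0, alpha=0.9).fit(A, B)
        diffs = np.diff(est.objective_trace_)
        assert (diffs <= 1e-12).all()

    def test_residual_monotone_in_lambda(self):
        A, B = _instance(12)
        fits = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            est = ew.MultiTaskGroupElasticNet(lam=lam, alpha=0.9,
                                              tol=1e-10).fit(A, B)
            fits.append(np.sum((A @ est.coef_full_ - B) ** 2))
        assert (np.diff(fits) >= -1e-9).all()

    def test_band_weights_require_column_grouping(self):
        A, B = _instance(13)
        with pytest.raises(ValueError, match="band_weights"):
            ew.MultiTaskGroupElasticNet(
                lam=1.0, alpha=0.9, grouping="node-rows",
                band_weights=np.ones(B.shape[1]),
            ).fit(A, B)

    def test_band_weights_scale_per_column_threshold(self):
        A, B = _instance(14, r=5, q=8, m=6)
        lam, alpha = 2.0, 0.8
        w = np.array([0.5, 1.0, 2.0, 1.0, 0.25, 3.0])
        est = ew.MultiTaskGroupElasticNet(
            lam=lam, alpha=alpha, grouping="coefficient-columns",
            band_weights=w, tol=1e-14, max_iter=50000,
        ).fit(A, B)
        # weighted problem separates: column k solves the single-group
        # problem with ridge weight lam*(1-alpha) and l1 weight lam*alpha*w_k
        def solve_col(k):
            lam_a = lam * alpha * w[k]
            lam_r = lam * (1 - alpha)
            tot = lam_a + lam_r
            return single_group_elastic_net(A, B[:, k], tot, lam_a / tot)

        expected = np.column_stack([solve_col(k) for k in range(B.shape[1])])
        np.testing.assert_allclose(est.coef_full_, expected, atol=1e-6)


class TestWaveletElasticNetPipeline:
    def test_unregularized_exact_recovery(self, geometry):
        """lam=0, square well-conditioned A, noiseless data: the pipeline
        returns the true potentials through transform and solve."""
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0, cv=1.0,
                                apd_base=100.0, duration=256.0)
        A = np.eye(geometry.n_heart)
        res = ew.reconstruct_wavelet_en(
            A, beat.phi_h_true,
            params=ew.RegularizationParams(lam=0.0, alpha=0.9),
        )
        err = np.abs(res.phi_h_hat.data - beat.phi_h_true.data).max()
        assert err < 1e-6 * np.abs(beat.phi_h_true.data).max()

    def test_full_shrinkage_gives_zero(self, fixture_pair, transfer):
        _, phi_b = fixture_pair
        res = ew.reconstruct_wavelet_en(
            transfer, phi_b,
            params=ew.RegularizationParams(lam=1e9, alpha=1.0),
        )
        assert np.abs(res.phi_h_hat.data).max() == 0.0
        assert np.abs(res.coeffs_hat.matrix).max() == 0.0

    def test_result_reports_mismatch_in_microvolts(self, fixture_pair, transfer):
        _, phi_b = fixture_pair
        res = ew.tikhonov_reconstruct(transfer, phi_b, lam=1e-3)
        direct = np.sqrt(np.mean(
            (transfer.entries @ res.phi_h_hat.data - phi_b.data) ** 2
        )) * 1000.0
        assert res.data_mismatch_uv == pytest.approx(direct, rel=1e-12)


class TestL1Sparsity:
    def test_zero_matrix(self):
        per_row, total = ew.l1_sparsity(np.zeros((3, 4)))
        assert total == 0.0
        np.testing.assert_array_equal(per_row, np.zeros(3))

    def test_hand_sum(self):
        per_row, total = ew.l1_sparsity(np.array([[1.0, -2.0, 3.0]]))
        assert per_row[0] == 6.0
        assert total == 6.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ew.l1_sparsity(np.array([[np.inf, 1.0]]))
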