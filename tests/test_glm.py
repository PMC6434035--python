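"""Smoothing, single-voxel GLM, lag sweep, prewhitening, thresholding."""

import numpy as np
import pytest
from scipy import stats

from bhcvr.glm import (
    fit_single,
    fraction_active,
    lag_sweep,
    nuisance_matrix,
    prewhiten_ar1,
    smooth,
    threshold_activation,
)

N = 73


def _design(bank, shift=0.0, detrend_order=3):
    nuis = nuisance_matrix(N, detrend_order, include_alternation=True)
    return np.column_stack([nuis, bank.row(shift)])


class TestSmooth:
    def test_constant_volume_unchanged_within_mask(self):
        mask = np.zeros((10, 10, 6), bool)
        mask[2:8, 2:8, 1:5] = True
        data = np.where(mask, 7.0, 0.0)[..., None]
        out = smooth(data, fwhm_mm=4.5, voxel_size_mm=3.0, mask=mask)
        np.testing.assert_allclose(out[mask], 7.0, atol=1e-10)
        assert not out[~mask].any()

    def test_impulse_fwhm(self):
        data = np.zeros((31, 31, 31, 1))
        data[15, 15, 15, 0] = 1.0
        out = smooth(data, fwhm_mm=4.5, voxel_size_mm=3.0)[..., 0]
        prof = out[:, 15, 15] / out[15, 15, 15]
        # Gaussian impulse response: sigma from the one-voxel log-ratio,
        # FWHM = 2*sqrt(2 ln 2)*sigma, expected 4.5 mm / 3 mm voxels
        sigma = np.sqrt(-0.5 / np.log(prof[16]))
        fwhm = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert fwhm == pytest.approx(4.5 / 3.0, rel=0.02)

    def test_smoothing_reduces_noise_variance(self, rng):
        data = rng.standard_normal((12, 12, 8, 5))
        out = smooth(data, fwhm_mm=4.5, voxel_size_mm=3.0)
        assert out.var() < 0.5 * data.var()


class TestFitSingle:
    def test_noiseless_fit_flags_infinite_t(self, bank):
        X = _design(bank)
        y = 10.0 + 3.0 * X[:, -1]
        beta, t, r2, resid = fit_single(y, X)
        assert beta == pytest.approx(3.0)
        assert np.isinf(t)
        assert r2 == 1.0
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_series_gives_zero_beta(self, bank):
        X = _design(bank)
        y = np.random.default_rng(0).standard_normal(N)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]  # residualize on the span
        beta, t, r2, _ = fit_single(y + 5.0 - 5.0, X)
        assert beta == pytest.approx(0.0, abs=1e-10)
        assert abs(t) < 1e-8

    def test_estimates_match_statsmodels_oracle(self, bank, rng):
        import statsmodels.api as sm

        X = _design(bank)
        y = X @ rng.standard_normal(X.shape[1]) + rng.standard_normal(N)
        beta, t, r2, resid = fit_single(y, X)
        fit = sm.OLS(y, X).fit()
        assert beta == pytest.approx(fit.params[-1], rel=1e-10)
        assert t == pytest.approx(fit.tvalues[-1], rel=1e-10)

    def test_known_beta_unbiased_and_se_analytic(self, bank, rng):
        # 1000-rep simulation: mean estimate ~ truth, empirical SE ~ (X'X)^-1 sigma^2
        X = _design(bank)
        true_beta, n_rep = 2.0, 1000
        Y = true_beta * X[:, -1:] + rng.standard_normal((N, n_rep))
        xtx_inv = np.linalg.inv(X.T @ X)
        betas = (xtx_inv @ X.T @ Y)[-1]
        se_analytic = np.sqrt(xtx_inv[-1, -1])
        assert betas.mean() == pytest.approx(true_beta, abs=4 * se_analytic / np.sqrt(n_rep))
        assert betas.std() == pytest.approx(se_analytic, rel=0.1)

    def test_rank_deficient_design_rejected(self, bank):
        X = _design(bank)
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            fit_single(np.zeros(N), X)


class TestLagSweep:
    def test_constructed_lag_recovered_exactly(self, bank):
        nuis = nuisance_matrix(N, 3, True)
        data = np.zeros((3, 1, 1, N))
        lags = [12.0, -8.0, 32.0]
        for i, s in enumerate(lags):
            data[i, 0, 0] = 100.0 + 5.0 * bank.row(s)
        res = lag_sweep(data, bank, nuis)
        np.testing.assert_array_equal(res.lag_s[:, 0, 0], lags)
        np.testing.assert_allclose(res.beta[:, 0, 0], 5.0, rtol=1e-9)
        np.testing.assert_allclose(res.r2[:, 0, 0], 1.0)
        assert res.lag_reliable.all()

    def test_max_t_at_least_any_single_shift(self, bank, rng):
        nuis = nuisance_matrix(N, 3, True)
        data = rng.standard_normal((4, 2, 1, N)) + 0.5 * bank.row(8.0)
        res = lag_sweep(data, bank, nuis)
        for s in bank.shifts_s:
            X = np.column_stack([nuis, bank.row(s)])
            for idx in np.ndindex(4, 2, 1):
                _, t, _, _ = fit_single(data[idx], X)
                assert res.tstat[idx] >= t - 1e-10

    def test_tie_breaks_toward_smaller_shift(self, bank):
        # two identical rows -> identical t; argmax picks the earlier shift
        from bhcvr.paradigm import RegressorBank

        row = bank.row(0.0)
        tied = RegressorBank(
            shifts_s=np.array([0.0, 4.0]),
            regressors=np.stack([row, row]),
        )
        rng = np.random.default_rng(3)
        data = (row + 0.1 * rng.standard_normal(N)).reshape(1, 1, 1, N)
        res = lag_sweep(data, tied, nuisance_matrix(N, 3, True))
        assert res.lag_s[0, 0, 0] == 0.0

    def test_scale_invariance_of_t_and_relative_beta(self, bank, rng):
        nuis = nuisance_matrix(N, 3, True)
        y = (100 + 5 * bank.row(4.0) + rng.standard_normal(N)).reshape(1, 1, 1, N)
        r1 = lag_sweep(y, bank, nuis)
        r2 = lag_sweep(3.7 * y, bank, nuis)
        assert r2.tstat[0, 0, 0] == pytest.approx(r1.tstat[0, 0, 0])
        assert r2.beta[0, 0, 0] == pytest.approx(3.7 * r1.beta[0, 0, 0])
        assert r2.lag_s[0, 0, 0] == r1.lag_s[0, 0, 0]

    def test_flagged_unreliable_when_no_positive_t(self, bank):
        # a deactivation (negative response at every shift) has t < 0
        # throughout the sweep, so the returned lag is flagged unreliable
        from bhcvr.paradigm import RegressorBank

        small = RegressorBank(
            shifts_s=np.array([0.0, 4.0]), regressors=bank.regressors[2:4]
        )
        nuis = nuisance_matrix(N, 0, include_alternation=False)
        y = 100.0 - 5.0 * small.regressors.sum(axis=0)
        y += 0.01 * np.random.default_rng(1).standard_normal(N)
        res = lag_sweep(y.reshape(1, 1, 1, N), small, nuis)
        assert res.tstat[0, 0, 0] < 0
        assert not res.lag_reliable[0, 0, 0]


class TestPrewhiten:
    def test_white_noise_rho_near_zero_matches_ols(self, bank, rng):
        X = _design(bank)
        Y = 2.0 * X[:, -1:] + rng.standard_normal((N, 200))
        beta_w, t_w, dof, rho, _ = prewhiten_ar1(Y, X)
        assert abs(rho.mean()) < 0.1  # white noise: no autocorrelation
        betas_o = np.linalg.lstsq(X, Y, rcond=None)[0][-1]
        np.testing.assert_allclose(beta_w, betas_o, atol=0.2)
        assert np.corrcoef(beta_w, betas_o)[0, 1] > 0.95

    def test_whitening_with_zero_rho_is_identity(self, bank):
        from bhcvr.glm import _whiten

        y = np.arange(10.0).reshape(-1, 1)
        np.testing.assert_array_equal(_whiten(y, np.array([0.0])), y)

    def test_extreme_rho_clamped(self):
        from bhcvr.glm import ar1_coefficient

        resid = np.ones((20, 1))  # lag-1 autocorr ~ 0.95 but ratio formula < 1
        resid[:, 0] = np.linspace(1, 2, 20)
        rho = ar1_coefficient(resid)
        assert np.all(np.abs(rho) <= 0.99)

    def test_too_few_frames_rejected(self, bank):
        with pytest.raises(ValueError, match="more than 10"):
            prewhiten_ar1(np.zeros((8, 1)), np.ones((8, 2)))


class TestThreshold:
    def test_student_quantile_dof60(self):
        from bhcvr.glm import ActivationResult

        res = ActivationResult(
            beta=np.zeros(3), tstat=np.array([3.0, 3.24, 4.0]), dof=60,
            lag_s=np.zeros(3), r2=np.zeros(3), fitted=np.zeros((3, 1)),
            lag_reliable=np.ones(3, bool),
        )
        # one-sided p<0.001 at dof 60: t ~ 3.232
        assert stats.t.ppf(0.999, 60) == pytest.approx(3.232, abs=5e-4)
        np.testing.assert_array_equal(
            threshold_activation(res, 0.001), [False, True, True]
        )

    def test_fraction_active_bounds(self):
        gm = np.ones((4, 4), bool)
        assert fraction_active(np.zeros((4, 4), bool), gm) == 0.0
        assert fraction_active(np.ones((4, 4), bool), gm) == 1.0
        with pytest.raises(ValueError, match="empty"):
            fraction_active(gm, np.zeros((4, 4), bool))
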