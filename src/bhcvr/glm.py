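"""Voxelwise breath-hold GLM with hemodynamic-lag optimization.

Each voxel's time series is fit against every lag-shifted BH regressor in
the bank (plus nuisance columns: intercept, Legendre drift terms and the
label/control alternation for BOLD data); the shift giving the highest
positive t-score is kept.  This lag sweep makes the test a maximum over
~11 correlated t-statistics, so the nominal per-voxel p-value is
anti-conservative under the null — a property of the procedure that is
documented and measured, not corrected.

Optional AR(1) prewhitening estimates the lag-1 residual autocorrelation
per voxel from the OLS residuals and refits by generalized least squares,
restoring approximately nominal type-I error under autocorrelated noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage, stats

from .paradigm import RegressorBank

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548
AR1_RHO_MAX = 0.99


def smooth(
    data_4d: np.ndarray,
    fwhm_mm: float = 4.5,
    voxel_size_mm: float | tuple[float, float, float] = 3.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Spatial Gaussian smoothing of each frame, optionally mask-normalized.

    sigma per axis is FWHM / (2*sqrt(2*ln 2)) / voxel size.  With a mask,
    the smoothed data are renormalized by the smoothed mask so values near
    the mask edge are unbiased; voxels outside the mask are zeroed.
    """
    if fwhm_mm == 0:
        return data_4d.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma = tuple(fwhm_mm / FWHM_TO_SIGMA / v for v in vs) + (0.0,)
    if mask is None:
        return ndimage.gaussian_filter(data_4d, sigma=sigma)
    m = mask.astype(float)[..., None]
    num = ndimage.gaussian_filter(data_4d * m, sigma=sigma)
    den = ndimage.gaussian_filter(np.broadcast_to(m, data_4d.shape).copy(), sigma=sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return out * m


def nuisance_matrix(
    n_frames: int,
    detrend_order: int = 3,
    include_alternation: bool = True,
) -> np.ndarray:
    """Nuisance design: intercept, Legendre trends, label/control alternation.

    The alternation column models the residual pCASL label/control
    oscillation and is used for BOLD designs only; PW designs pass
    ``include_alternation=False`` and ``detrend_order=0`` (the PW series is
    already filtered).
    """
    x = np.linspace(-1.0, 1.0, n_frames)
    cols = [legendre.legvander(x, detrend_order)]
    if include_alternation:
        cols.append(np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)[:, None])
    return np.concatenate(cols, axis=1)


@dataclass
class ActivationResult:
    """Voxelwise BH activation after lag optimization.

    beta is the response amplitude in signal units (the regressor is unit
    peak, so beta is the peak response); lag_s the chosen shift; r2 the
    variance explained by the BH regressor after nuisance projection;
    lag_reliable is False where no shift produced a positive t.
    """

    beta: np.ndarray
    tstat: np.ndarray
    dof: int
    lag_s: np.ndarray
    r2: np.ndarray
    fitted: np.ndarray
    lag_reliable: np.ndarray
    active_mask_p001: np.ndarray | None = None


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = np.where(np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max())[0]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns); collinear columns: {bad.tolist()}"
        )


def _ols(Y: np.ndarray, X: np.ndarray):
    """OLS of Y (t, v) on X (t, p): beta (p, v), residuals (t, v), (X'X)^-1."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    return beta, resid, xtx_inv


def _tstats(beta_j, resid, xtx_inv_jj, dof, yss=None):
    """t = beta/SE; residual variance numerically zero -> t flagged +/-inf.

    yss (per-voxel sum of squares of the demeaned data) sets the scale for
    deciding that a residual is zero, so noiseless fits flag cleanly.
    """
    ss = np.sum(resid**2, axis=0)
    zero = ss == 0 if yss is None else ss <= 1e-18 * np.maximum(yss, 1e-300)
    sigma2 = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_j / np.sqrt(sigma2 * xtx_inv_jj)
    t[zero & (beta_j > 0)] = np.inf
    t[zero & (beta_j < 0)] = -np.inf
    t[zero & (beta_j == 0)] = 0.0
    return t


def fit_single(y: np.ndarray, design: np.ndarray, reg_col: int = -1):
    """OLS fit of one voxel series against a full design.

    Returns (beta, t, r2, residuals) for the regressor-of-interest column
    (default: last).  r2 is the fraction of variance explained by that
    regressor after projecting out the remaining (nuisance) columns; a
    noiseless fit yields t = +/-inf and r2 = 1.
    """
    y = np.asarray(y, dtype=float)
    _check_full_rank(design)
    p = design.shape[1]
    dof = len(y) - p
    beta, resid, xtx_inv = _ols(y[:, None], design)
    reg_col = reg_col % p
    yss = np.sum((y - y.mean()) ** 2)[None]
    t = _tstats(beta[reg_col], resid, xtx_inv[reg_col, reg_col], dof, yss)[0]
    r2 = _r2_from_t(np.asarray(t), dof)[()]
    return beta[reg_col, 0], t, r2, resid[:, 0]


def _r2_from_t(t: np.ndarray, dof: int) -> np.ndarray:
    """Partial variance explained by one regressor: r2 = t^2 / (t^2 + dof)."""
    with np.errstate(invalid="ignore"):
        r2 = np.where(np.isinf(t), 1.0, t**2 / (t**2 + dof))
    return np.where(np.isnan(t), np.nan, r2)


def ar1_coefficient(resid: np.ndarray, bias_correct: bool = True) -> np.ndarray:
    """Lag-1 autocorrelation of residuals (t, v), clamped to |rho| <= 0.99.

    The naive estimator is biased low by ~(1 + 3 rho)/n in short series;
    the standard first-order correction is applied by default so the
    whitened test keeps its nominal size at fMRI-scale frame counts.
    """
    n = resid.shape[0]
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    if bias_correct:
        rho = rho + (1.0 + 3.0 * rho) / n
    return np.clip(rho, -AR1_RHO_MAX, AR1_RHO_MAX)


def _whiten(arr: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """AR(1) whitening along axis 0; rho broadcasts over trailing axes."""
    out = np.empty_like(arr)
    out[0] = np.sqrt(1.0 - rho**2) * arr[0]
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def prewhiten_ar1(Y: np.ndarray, X: np.ndarray, reg_col: int = -1):
    """AR(1)-prewhitened GLS fit of Y (t, v) on X (t, p).

    rho is estimated per voxel from OLS residuals, the series and design
    are whitened (first observation scaled by sqrt(1-rho^2)), and the model
    is refit.  Returns (beta_j, t_j, dof, rho, fitted) where fitted is the
    unwhitened model prediction X @ beta.
    """
    n, p = X.shape
    if n <= 10:
        raise ValueError(f"AR(1) prewhitening needs more than 10 frames, got {n}")
    reg_col = reg_col % p
    _, resid, _ = _ols(Y, X)
    rho = ar1_coefficient(resid)  # (v,)
    Yw = _whiten(Y, rho[None, :])
    Xw = _whiten(np.broadcast_to(X[:, :, None], (n, p, len(rho))), rho[None, None, :])
    Xw = np.moveaxis(Xw, 2, 0)  # (v, t, p)
    A = Xw.transpose(0, 2, 1) @ Xw  # (v, p, p)
    b = np.einsum("vtp,tv->vp", Xw, Yw)
    beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]  # (v, p)
    A_inv = np.linalg.inv(A)
    resid_w = Yw - np.einsum("vtp,vp->tv", Xw, beta)
    dof = n - p
    yss = np.sum((Yw - Yw.mean(axis=0)) ** 2, axis=0)
    t = _tstats(beta[:, reg_col], resid_w, A_inv[:, reg_col, reg_col], dof, yss)
    fitted = X @ beta.T
    return beta[:, reg_col], t, dof, rho, fitted


def lag_sweep(
    data_4d: np.ndarray,
    bank: RegressorBank,
    nuisance: np.ndarray,
    mask: np.ndarray | None = None,
    prewhiten: bool = False,
    p_thresh: float = 0.001,
) -> ActivationResult:
    """Fit every lag-shifted regressor per voxel and keep the best.

    For each shift the design is [nuisance | shifted regressor]; the shift
    with the highest positive t wins (ties toward the smaller shift).  If
    no shift gives t > 0 the maximal-t fit is returned with the lag flagged
    unreliable.  The returned mask thresholds the one-sided t at p_thresh.
    """
    if bank.n_shifts == 0:
        raise ValueError("regressor bank is empty")
    grid = data_4d.shape[:-1]
    n = data_4d.shape[-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    Y = data_4d[mask].T  # (t, v)
    nv = Y.shape[1]

    betas = np.empty((bank.n_shifts, nv))
    tstats = np.empty((bank.n_shifts, nv))
    fits = np.empty((bank.n_shifts, n, nv))
    dof = n - (nuisance.shape[1] + 1)
    for i in range(bank.n_shifts):
        X = np.column_stack([nuisance, bank.regressors[i]])
        _check_full_rank(X)
        if prewhiten:
            b, t, dof, _, fitted = prewhiten_ar1(Y, X)
            betas[i], tstats[i], fits[i] = b, t, fitted
        else:
            beta, resid, xtx_inv = _ols(Y, X)
            betas[i] = beta[-1]
            yss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
            tstats[i] = _tstats(beta[-1], resid, xtx_inv[-1, -1], dof, yss)
            fits[i] = X @ beta

    best = np.argmax(tstats, axis=0)  # first max -> smallest shift on ties
    idx = (best, np.arange(nv))
    t_best = tstats[idx]
    result = ActivationResult(
        beta=_scatter(betas[idx], mask),
        tstat=_scatter(t_best, mask),
        dof=dof,
        lag_s=_scatter(bank.shifts_s[best], mask),
        r2=_scatter(_r2_from_t(t_best, dof), mask),
        fitted=_scatter_series(fits[best, :, np.arange(nv)].T, mask, n),
        lag_reliable=_scatter(t_best > 0, mask, fill=False),
    )
    result.active_mask_p001 = threshold_activation(result, p=p_thresh)
    return result


def _scatter(values: np.ndarray, mask: np.ndarray, fill=np.nan) -> np.ndarray:
    out = np.full(mask.shape, fill, dtype=values.dtype if values.dtype == bool else float)
    out[mask] = values
    return out


def _scatter_series(values_tv: np.ndarray, mask: np.ndarray, n: int) -> np.ndarray:
    out = np.full(mask.shape + (n,), np.nan)
    out[mask] = values_tv.T
    return out


def threshold_activation(result: ActivationResult, p: float = 0.001) -> np.ndarray:
    """One-sided activation mask: t above the Student quantile at the dof."""
    if result.dof <= 0:
        raise ValueError(f"non-positive residual dof: {result.dof}")
    tcrit = stats.t.ppf(1.0 - p, result.dof)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(result.tstat, nan=-np.inf) > tcrit


def fraction_active(active_mask: np.ndarray, gm_mask: np.ndarray) -> float:
    """Fraction of gray-matter voxels inside the activation mask."""
    n_gm = int(np.sum(gm_mask))
    if n_gm == 0:
        raise ValueError("gray-matter mask is empty")
    return float(np.sum(active_mask & gm_mask) / n_gm)
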