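"""Multi-echo handling: T2* fitting, echo combination weights, tSNR.

Across echo time TE the gradient-echo signal decays as
S(TE) = S0 * exp(-TE / T2*).  Fitting the time-averaged signal of each echo
to this exponential (log-linear least squares) gives voxelwise S0 and T2*;
the echoes are then combined by a weighted sum with weights

    w_n = TE_n * exp(-TE_n / T2*) / sum_n TE_n * exp(-TE_n / T2*),

which up-weights the echo nearest the voxel's T2*, where BOLD contrast is
maximal.  Temporal SNR is mean signal over the standard deviation of the
residual noise around the model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

# admissible T2* range (ms); fits outside are flagged invalid
T2STAR_MIN_MS = 2.0
T2STAR_MAX_MS = 300.0

# label/control frame-parity conventions (0-based frame index)
EVEN_CONTROL = "even-control"
EVEN_LABEL = "even-label"


@dataclass
class MultiEchoSeries:
    """Per-echo 4-D voxel time series plus acquisition metadata.

    data has shape (n_echoes, nx, ny, nz, n_frames); te_ms is strictly
    increasing; label_parity records which frame parity carries the ASL
    label ("even-control" means even frames are control).
    """

    data: np.ndarray
    te_ms: np.ndarray
    tr_s: float
    label_parity: str = EVEN_CONTROL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("data must be (n_echoes, nx, ny, nz, n_frames)")
        if len(self.te_ms) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.te_ms)} echo times for {self.data.shape[0]} echo volumes"
            )
        if len(self.te_ms) and (
            np.any(np.diff(self.te_ms) <= 0) or np.any(self.te_ms <= 0)
        ):
            raise ValueError("te_ms must be positive and strictly increasing")
        if self.label_parity not in (EVEN_CONTROL, EVEN_LABEL):
            raise ValueError(f"unknown label_parity {self.label_parity!r}")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]

    def echo(self, index: int) -> np.ndarray:
        """One echo's 4-D series (nx, ny, nz, n_frames)."""
        return self.data[index]

    def control_sign(self) -> np.ndarray:
        """Per-frame +1 on control frames, -1 on label frames."""
        n = np.arange(self.n_frames)
        sign = np.where(n % 2 == 0, 1.0, -1.0)
        return sign if self.label_parity == EVEN_CONTROL else -sign

    def with_data(self, data: np.ndarray) -> "MultiEchoSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class T2StarMap:
    """Voxelwise mono-exponential decay fit: T2* (ms), S0, validity mask."""

    t2star_ms: np.ndarray
    s0: np.ndarray
    valid_mask: np.ndarray


@dataclass
class EchoWeights:
    """Per-voxel echo-combination weights, (n_echoes, nx, ny, nz)."""

    w: np.ndarray
    valid_mask: np.ndarray


def fit_t2star(series: MultiEchoSeries) -> T2StarMap:
    """Log-linear T2* fit on the time-averaged signal of each echo.

    Ordinary least squares of ln(mean signal) against echo time:
    slope = -1/T2*, intercept = ln(S0).  Voxels with a non-positive mean at
    any echo, or a fitted T2* outside [2, 300] ms, are flagged invalid (NaN
    maps) rather than raising.
    """
    if series.n_echoes < 2:
        raise ValueError("T2* fitting requires at least 2 echoes")
    means = series.data.mean(axis=-1)  # (E, nx, ny, nz)
    valid = np.all(means > 0, axis=0)

    logm = np.where(means > 0, np.log(np.where(means > 0, means, 1.0)), 0.0)
    te = series.te_ms
    te_c = te - te.mean()
    denom = np.sum(te_c**2)
    slope = np.tensordot(te_c, logm, axes=(0, 0)) / denom
    intercept = logm.mean(axis=0) - slope * te.mean()

    with np.errstate(divide="ignore", invalid="ignore"):
        t2star = -1.0 / slope
    s0 = np.exp(intercept)
    valid &= np.isfinite(t2star) & (t2star >= T2STAR_MIN_MS) & (t2star <= T2STAR_MAX_MS)

    t2star = np.where(valid, t2star, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return T2StarMap(t2star_ms=t2star, s0=s0, valid_mask=valid)


def compute_weights(t2s: T2StarMap, te_ms: np.ndarray) -> EchoWeights:
    """Echo weights TE_n * exp(-TE_n/T2*), normalized per voxel.

    Invalid voxels get uniform weights and stay flagged in valid_mask.
    """
    te = np.asarray(te_ms, dtype=float).reshape((-1,) + (1,) * t2s.t2star_ms.ndim)
    with np.errstate(invalid="ignore", over="ignore"):
        raw = te * np.exp(-te / t2s.t2star_ms)
        w = raw / raw.sum(axis=0)
    uniform = np.full_like(w, 1.0 / len(te_ms))
    w = np.where(t2s.valid_mask, w, uniform)
    return EchoWeights(w=w, valid_mask=t2s.valid_mask)


def combine(series: MultiEchoSeries, weights: EchoWeights) -> np.ndarray:
    """T2*-weighted echo combination: per frame, sum_e w_e * S_e.

    Weights are constant over time.  Returns a 4-D array (nx, ny, nz, t).
    """
    if weights.w.shape != series.data.shape[:-1]:
        raise ValueError(
            f"weight shape {weights.w.shape} does not match "
            f"echo volumes {series.data.shape[:-1]}"
        )
    return np.einsum("exyz,exyzt->xyzt", weights.w, series.data)


def tsnr(series_4d: np.ndarray, fitted_4d: np.ndarray) -> np.ndarray:
    """Temporal SNR: mean(signal) / sd(signal - model fit), per voxel.

    Zero residual variance (a perfect fit) yields +/-inf rather than an
    error, flagging the voxel.
    """
    if series_4d.shape != fitted_4d.shape:
        raise ValueError("series and fitted model must share a shape")
    mean = series_4d.mean(axis=-1)
    sd = (series_4d - fitted_4d).std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / sd
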