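"""BOLD cleaning and perfusion-weighted (PW) series extraction.

A pCASL tagging module alternates label and control frames, superimposing a
Nyquist-frequency oscillation on every echo.  For the BOLD analysis that
oscillation is a nuisance and is regressed out (a +/-1 alternation column).
For perfusion, the shortest echo — where the label/control difference is
least T2*-attenuated — is high-pass filtered above 0.09 Hz and demodulated
by cos(pi*n) = (-1)^n, shifting the Nyquist alternation down to DC and
yielding a perfusion-weighted time series whose positive values mean
control > label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .echoes import MultiEchoSeries


@dataclass
class PwSeries:
    """Perfusion-weighted 4-D series derived from the first echo."""

    data: np.ndarray
    source_echo: int = 0
    cutoff_hz: float = 0.09
    tr_s: float = 4.0


def _alternation(n_frames: int) -> np.ndarray:
    return np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)


def regress_label_control(data_4d: np.ndarray) -> np.ndarray:
    """Project the (-1)^n label/control alternation out of each voxel series.

    The alternation is fit jointly with an intercept (they are not exactly
    orthogonal over an odd frame count) and only the alternation component
    is subtracted, so b + d*(-1)^n maps exactly to b and the voxel mean
    survives.
    """
    n = data_4d.shape[-1]
    if n < 4:
        raise ValueError(f"need at least 4 frames, got {n}")
    a = _alternation(n)
    X = np.column_stack([np.ones(n), a])
    Y = data_4d.reshape(-1, n).T  # (t, v)
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    cleaned = Y - np.outer(a, beta[1])
    return cleaned.T.reshape(data_4d.shape)


def detrend_poly(data_4d: np.ndarray, order: int = 3) -> np.ndarray:
    """Remove Legendre polynomial trends up to ``order``; the mean survives.

    Slow drifts are modelled by Legendre polynomials of degree 1..order on
    [-1, 1]; the degree-0 (mean) component is fitted jointly but re-added,
    so percent-signal-change baselines are preserved.
    """
    n = data_4d.shape[-1]
    if n <= order + 1:
        raise ValueError(f"need more than {order + 1} frames, got {n}")
    x = np.linspace(-1.0, 1.0, n)
    X = legendre.legvander(x, order)  # (t, order+1), column 0 constant
    # demean the trend columns so removing them leaves the sample mean exact
    X[:, 1:] -= X[:, 1:].mean(axis=0)
    Y = data_4d.reshape(-1, n).T
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    trend = X[:, 1:] @ beta[1:]
    return (Y - trend).T.reshape(data_4d.shape)


def pw_from_echo1(
    series: MultiEchoSeries,
    cutoff_hz: float = 0.09,
    filter_order: int = 4,
) -> PwSeries:
    """High-pass + demodulate the first echo into a PW series.

    Each voxel series is high-pass filtered (zero-phase forward-backward
    Butterworth of the given order) above ``cutoff_hz``, then multiplied by
    (-1)^n, oriented by the label parity so that positive PW means
    control > label.
    """
    nyquist = 0.5 / series.tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz "
            f"for TR = {series.tr_s} s"
        )
    echo1 = series.echo(0)
    sos = signal.butter(filter_order, cutoff_hz, btype="highpass", fs=1.0 / series.tr_s, output="sos")
    filtered = signal.sosfiltfilt(sos, echo1, axis=-1, padtype="even")
    demod = filtered * series.control_sign()
    return PwSeries(data=demod, source_echo=0, cutoff_hz=cutoff_hz, tr_s=series.tr_s)


def pw_filtered_bank(bank, tr_s: float, cutoff_hz: float = 0.09, filter_order: int = 4):
    """Pass each BH regressor through the PW measurement operator.

    A perfusion response of shape r(n) enters the raw echo-1 series as
    (-1)^n * r(n); after the high-pass and demodulation it emerges as
    (-1)^n * F[(-1)^n * r](n), where F is the zero-phase filter.  Fitting
    the PW series against that transformed regressor (rather than r
    itself) keeps the beta an unbiased estimate of the response amplitude
    — the cutoff clips BH-response harmonics whose mirrored frequencies
    fall below it, so the raw regressor would be mismatched to the data.
    """
    from .paradigm import RegressorBank

    n = bank.n_frames
    parity = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    sos = signal.butter(filter_order, cutoff_hz, btype="highpass", fs=1.0 / tr_s, output="sos")
    rows = parity * signal.sosfiltfilt(sos, parity * bank.regressors, axis=-1, padtype="even")
    return RegressorBank(
        shifts_s=bank.shifts_s, regressors=rows, hrf_params=bank.hrf_params, dt=bank.dt
    )
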