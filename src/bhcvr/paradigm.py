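"""Breath-hold task schedule and lag-shifted regressor bank.

The breath-hold (BH) paradigm is a block design: an initial stretch of paced
breathing, several cycles of (breath-hold, self-paced recovery, paced
breathing), and a paced-breathing tail.  The scanner additionally acquires
calibration frames at the start of the run that are discarded before
analysis, so the model clock starts at the first retained frame.

Because the hemodynamic response to a breath-hold is slow and its delay
varies across the brain by several seconds, the BH regressor (boxcar
convolved with a double-gamma HRF) is evaluated at a bank of time shifts;
downstream the GLM picks, per voxel, the shift with the highest positive
t-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Paradigm:
    """Breath-hold block schedule (all durations in seconds)."""

    lead_in_s: float = 44.0
    n_cycles: int = 4
    bh_s: float = 16.0
    recovery_s: float = 16.0
    paced_s: float = 24.0
    tail_s: float = 24.0
    calibration_s: float = 64.0
    tr_s: float = 4.0

    @property
    def total_duration_s(self) -> float:
        return (
            self.calibration_s
            + self.lead_in_s
            + self.n_cycles * (self.bh_s + self.recovery_s + self.paced_s)
            + self.tail_s
        )

    @property
    def functional_duration_s(self) -> float:
        """Scan time that survives removal of the calibration period."""
        return self.total_duration_s - self.calibration_s

    @property
    def n_frames(self) -> int:
        return int(round(self.functional_duration_s / self.tr_s))

    def bh_onsets_s(self) -> np.ndarray:
        """Breath-hold onset times on the functional clock (calibration excluded)."""
        cycle = self.bh_s + self.recovery_s + self.paced_s
        return self.lead_in_s + cycle * np.arange(self.n_cycles)

    def frame_times_s(self) -> np.ndarray:
        return self.tr_s * np.arange(self.n_frames)


def build_paradigm(**fields) -> Paradigm:
    """Validate and construct a :class:`Paradigm`.

    Raises
    ------
    ValueError
        If any duration is non-positive (n_cycles and the optional
        lead-in/tail/calibration may be zero), or if the functional duration
        is not an integer multiple of the repetition time.
    """
    p = Paradigm(**fields)
    if p.tr_s <= 0:
        raise ValueError(f"tr_s must be positive, got {p.tr_s}")
    if p.n_cycles < 0:
        raise ValueError(f"n_cycles must be non-negative, got {p.n_cycles}")
    if p.n_cycles > 0 and min(p.bh_s, p.recovery_s, p.paced_s) <= 0:
        raise ValueError(
            "cycle durations must be positive: "
            f"bh_s={p.bh_s}, recovery_s={p.recovery_s}, paced_s={p.paced_s}"
        )
    if min(p.lead_in_s, p.tail_s, p.calibration_s) < 0:
        raise ValueError("lead_in_s, tail_s and calibration_s must be >= 0")
    n = p.functional_duration_s / p.tr_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"functional duration {p.functional_duration_s} s is not an "
            f"integer multiple of tr_s={p.tr_s} s (check lead_in_s={p.lead_in_s}, "
            f"bh_s={p.bh_s}, recovery_s={p.recovery_s}, paced_s={p.paced_s}, "
            f"tail_s={p.tail_s})"
        )
    return p


def boxcar(paradigm: Paradigm, dt: float) -> np.ndarray:
    """Sample the BH indicator (1 during breath-holds, 0 otherwise) at step dt.

    The calibration period is excluded: sample k sits at time k*dt on the
    functional clock.  dt must divide every block duration.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    durations = [
        paradigm.lead_in_s,
        paradigm.bh_s,
        paradigm.recovery_s,
        paradigm.paced_s,
        paradigm.tail_s,
    ]
    for d in durations:
        if abs(d / dt - round(d / dt)) > 1e-9:
            raise ValueError(f"dt={dt} does not divide block duration {d} s")
    n = int(round(paradigm.functional_duration_s / dt))
    t = dt * np.arange(n)
    out = np.zeros(n)
    for onset in paradigm.bh_onsets_s():
        out[(t >= onset - 1e-9) & (t < onset + paradigm.bh_s - 1e-9)] = 1.0
    return out


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


def double_gamma_hrf(dt: float, params: HrfParams | None = None) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, normalized to unit peak.

    The kernel is the difference of two gamma densities — a positive main
    lobe peaking ~5 s after onset and a delayed undershoot — evaluated on a
    grid of step ``dt`` over ``params.duration_s`` seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or HrfParams()
    t = dt * np.arange(int(round(p.duration_s / dt)) + 1)
    peak = stats.gamma.pdf(
        t, p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s
    )
    under = stats.gamma.pdf(
        t,
        p.undershoot_delay_s / p.undershoot_dispersion_s,
        scale=p.undershoot_dispersion_s,
    )
    h = peak - p.undershoot_ratio * under
    return h / h.max()


@dataclass(frozen=True)
class RegressorBank:
    """Lag-shifted BH regressors sampled on the frame grid.

    ``regressors[i]`` is the predicted unit-peak BH response delayed by
    ``shifts_s[i]`` seconds, sampled at the frame times.
    """

    shifts_s: np.ndarray
    regressors: np.ndarray  # (n_shifts, n_frames)
    hrf_params: HrfParams = field(default_factory=HrfParams)
    dt: float = 0.1

    @property
    def n_shifts(self) -> int:
        return len(self.shifts_s)

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[1]

    def row(self, shift_s: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.shifts_s - shift_s)))
        if abs(self.shifts_s[i] - shift_s) > 1e-9:
            raise KeyError(f"shift {shift_s} s not in bank")
        return self.regressors[i]


def default_shifts(tr_s: float) -> np.ndarray:
    """Shift grid −2·TR … +8·TR in steps of TR (11 shifts)."""
    return tr_s * np.arange(-2, 9, dtype=float)


def build_regressor_bank(
    paradigm: Paradigm,
    shifts_s: np.ndarray | None = None,
    hrf_params: HrfParams | None = None,
    dt: float = 0.1,
) -> RegressorBank:
    """Convolve the BH boxcar with the HRF and shift/resample onto frames.

    The convolution runs on a fine grid (default 0.1 s, which divides all
    paradigm durations) with zero-padding at the edges; the convolved
    response is scaled to unit peak, time-shifted, and sampled at the frame
    times.  Shifted responses extending past the last frame are truncated.
    """
    hrf_params = hrf_params or HrfParams()
    if shifts_s is None:
        shifts_s = default_shifts(paradigm.tr_s)
    shifts_s = np.asarray(shifts_s, dtype=float)

    box = boxcar(paradigm, dt)
    hrf = double_gamma_hrf(dt, hrf_params)
    resp = np.convolve(box, hrf)[: len(box)] * dt
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    t_fine = dt * np.arange(len(resp))
    t_frames = paradigm.frame_times_s()

    rows = np.empty((len(shifts_s), len(t_frames)))
    for i, s in enumerate(shifts_s):
        # response delayed by s: value at t is resp(t - s), zero outside support
        rows[i] = np.interp(t_frames - s, t_fine, resp, left=0.0, right=0.0)
        if peak > 0 and not np.any(rows[i] != 0.0):
            raise ValueError(
                f"shift {s} s pushes the regressor support entirely outside "
                f"the {paradigm.functional_duration_s}-s scan"
            )
    return RegressorBank(shifts_s=shifts_s, regressors=rows, hrf_params=hrf_params, dt=dt)
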