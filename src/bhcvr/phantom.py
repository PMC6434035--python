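"""Synthetic 4-echo ASL/BOLD phantom with known ground truth.

The phantom emulates the acquisition the pipeline targets: four echoes read
out per frame, alternating pCASL label/control frames, and a breath-hold
block paradigm driving a lagged vasodilatory response.  Every downstream
quantity the pipeline estimates — T2*, echo weights, BH lag, CVR, CBF
ratio, Davis M — has a known per-voxel truth here, so the pipeline's
accuracy is measurable without scanner data.

Signal model per voxel v, frame n, echo e (TE in ms):

    S_e(n) = S0_v(n) * exp(-TE_e / T2*_v) * exp(-TE_e * dR2*_v(n)) + noise

    dR2*_v(n) = -ln(1 + CVR_v) / TE_ref * reg_v(n)
    S0_v(n)   = S0_v + A_v * s(n) * (1 + (f_v - 1) * reg_v(n))

where reg_v is the unit-peak BH regressor delayed by the voxel's lag,
TE_ref = 25 ms is the reference echo time at which the fractional BOLD
change equals the CVR truth CVR_v, s(n) = +/-1 is the control/label parity,
A_v the perfusion alternation amplitude, and f_v the CBF/CBF0 ratio during
the hold.  The BOLD effect enters as a T2* (rate) change, so its percent
amplitude grows with TE and echo combination demonstrably averages CVR
across echo times; the perfusion alternation rides on S0 and decays with
TE, dominating echo 1.  Noise is white Gaussian per echo/frame, optionally
AR(1)-correlated in time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .echoes import EVEN_CONTROL, MultiEchoSeries
from .paradigm import Paradigm, RegressorBank, build_regressor_bank

DEFAULT_TE_MS = (9.1, 25.0, 39.6, 54.3)
REFERENCE_TE_MS = 25.0


@dataclass
class PhantomTruth:
    """Ground-truth maps for the synthetic phantom (all 3-D, one grid)."""

    gm_mask: np.ndarray
    wm_mask: np.ndarray
    s0_map: np.ndarray
    t2star_ms: np.ndarray
    lag_map_s: np.ndarray
    cvr_truth: np.ndarray  # fractional BOLD change at the reference TE
    cbf_ratio_truth: np.ndarray  # CBF/CBF0 during breath-hold
    perfusion_amp: np.ndarray  # label/control alternation amplitude (signal units)
    noise_sd: float = 5.0
    ar1_rho: float = 0.0
    seed: int = 0
    te_ms: tuple = DEFAULT_TE_MS
    reference_te_ms: float = REFERENCE_TE_MS

    def __post_init__(self) -> None:
        if np.any(self.gm_mask & self.wm_mask):
            raise ValueError("GM and WM masks must be disjoint")
        brain = self.brain_mask
        if np.any(self.t2star_ms[brain] <= 0):
            raise ValueError("t2star_ms must be positive inside the brain")
        if np.any(self.cbf_ratio_truth[brain] <= 0):
            raise ValueError("cbf_ratio_truth must be positive inside the brain")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.gm_mask | self.wm_mask

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.gm_mask.shape


def default_truth(
    shape: tuple[int, int, int] = (12, 12, 8),
    tr_s: float = 4.0,
    noise_sd: float = 5.0,
    ar1_rho: float = 0.0,
    seed: int = 0,
    gm_cvr: float = 0.017,
    gm_cbf_ratio: float = 1.5,
    wm_cbf_ratio: float = 1.25,
    gm_t2star_ms: float = 25.0,
    wm_t2star_ms: float = 22.0,
    gm_s0: float = 1000.0,
    wm_s0: float = 900.0,
    gm_perfusion_amp: float = 10.0,
    wm_perfusion_amp: float = 4.0,
) -> PhantomTruth:
    """Concentric-geometry default phantom: WM core wrapped in a GM ring.

    Default tissue values emulate whole-tissue 3 T EPI behaviour: GM CVR
    1.7% at TE 25 ms with WM at half that, GM CBF ratio 1.5 during the
    hold, a perfusion alternation of ~1% of S0 in GM, and *effective*
    mono-exponential T2* of 25 ms (GM) / 22 ms (WM).  The effective values
    sit well below single-voxel tissue T2* because the log-linear fit on
    magnitude EPI averaged over a whole tissue class absorbs macroscopic
    field-inhomogeneity dephasing; they also place the signal-weighted
    effective echo time of the T2*-weighted combination below the second
    echo, so combined-echo CVR comes out lower than single-echo CVR, the
    behaviour observed in vivo.  Response lags
    sweep the full -2·TR..8·TR shift grid in contiguous diagonal bands, so
    lag recovery is exercised at every shift while neighbouring voxels keep
    similar delays, as in real vascular territories.
    """
    nx, ny, nz = shape
    ix, iy, iz = np.indices(shape)
    # central WM core, one-voxel padding to the volume edge for the GM ring
    core = (
        (ix >= nx // 4) & (ix < nx - nx // 4)
        & (iy >= ny // 4) & (iy < ny - ny // 4)
        & (iz >= nz // 4) & (iz < nz - nz // 4)
    )
    shell = (
        (ix >= 1) & (ix < nx - 1)
        & (iy >= 1) & (iy < ny - 1)
        & (iz >= 1) & (iz < nz - 1)
    )
    wm_mask = core
    gm_mask = shell & ~core

    t2 = np.where(gm_mask, gm_t2star_ms, np.where(wm_mask, wm_t2star_ms, 20.0))
    s0 = np.where(gm_mask, gm_s0, np.where(wm_mask, wm_s0, 0.0))
    cvr = np.where(gm_mask, gm_cvr, np.where(wm_mask, gm_cvr / 2.0, 0.0))
    cbf = np.where(gm_mask, gm_cbf_ratio, np.where(wm_mask, wm_cbf_ratio, 1.0))
    amp = np.where(gm_mask, gm_perfusion_amp, np.where(wm_mask, wm_perfusion_amp, 0.0))

    # lags vary smoothly in space: contiguous diagonal bands sweep the full
    # shift grid, so every shift occurs in-brain but neighbours mostly agree
    shifts = tr_s * np.arange(-2, 9, dtype=float)
    diag = (ix - 1) + (iy - 1)
    band = np.clip(diag, 0, None) * len(shifts) // ((nx - 3) + (ny - 3) + 1)
    lag = np.where(gm_mask | wm_mask, shifts[np.clip(band, 0, len(shifts) - 1)], 0.0)

    return PhantomTruth(
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        s0_map=s0,
        t2star_ms=t2,
        lag_map_s=lag,
        cvr_truth=cvr,
        cbf_ratio_truth=cbf,
        perfusion_amp=amp,
        noise_sd=noise_sd,
        ar1_rho=ar1_rho,
        seed=seed,
    )


def _noise(rng, shape, sd, rho):
    eps = rng.standard_normal(shape)
    if rho != 0.0:
        # AR(1) innovation scaling keeps the marginal variance at sd^2
        out = np.empty_like(eps)
        out[..., 0] = eps[..., 0]
        scale = np.sqrt(1.0 - rho**2)
        for t in range(1, shape[-1]):
            out[..., t] = rho * out[..., t - 1] + scale * eps[..., t]
        eps = out
    return sd * eps


def generate_phantom(
    truth: PhantomTruth,
    paradigm: Paradigm,
    bank: RegressorBank | None = None,
    seed: int | None = None,
) -> MultiEchoSeries:
    """Render the phantom truth into a 4-echo time series.

    The same regressor construction used by the analysis (boxcar * HRF,
    unit peak, shifted) drives the simulated response, evaluated at each
    voxel's true lag.  A fixed seed gives bit-identical output.
    """
    if paradigm.n_frames < 2:
        raise ValueError("paradigm must yield at least 2 frames")
    if bank is None:
        bank = build_regressor_bank(paradigm, shifts_s=np.unique(truth.lag_map_s))
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    n = paradigm.n_frames
    grid = truth.grid_shape
    te = np.asarray(truth.te_ms, dtype=float)

    # per-voxel regressor at the true lag, (x, y, z, t)
    reg = np.zeros(grid + (n,))
    for s in np.unique(truth.lag_map_s[truth.brain_mask]):
        sel = truth.brain_mask & (truth.lag_map_s == s)
        reg[sel] = bank.row(s)

    parity = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # +1 = control
    with np.errstate(divide="ignore"):
        delta_r2 = np.where(
            truth.brain_mask,
            -np.log1p(truth.cvr_truth) / truth.reference_te_ms,
            0.0,
        )
    cbf_mod = 1.0 + (truth.cbf_ratio_truth[..., None] - 1.0) * reg
    s0_t = (
        truth.s0_map[..., None]
        + truth.perfusion_amp[..., None] * parity * cbf_mod
    )

    data = np.empty((len(te),) + grid + (n,))
    for e, te_e in enumerate(te):
        decay = np.exp(-te_e / truth.t2star_ms)[..., None]
        bold = np.exp(-te_e * delta_r2[..., None] * reg)
        clean = s0_t * decay * bold
        if np.any(clean[truth.brain_mask] <= 0):
            raise ValueError(
                "non-positive noiseless signal; lower the perfusion amplitude "
                "or CVR modulation"
            )
        data[e] = clean + _noise(rng, grid + (n,), truth.noise_sd, truth.ar1_rho)

    return MultiEchoSeries(
        data=data, te_ms=te, tr_s=paradigm.tr_s, label_parity=EVEN_CONTROL
    )


def second_session(
    truth: PhantomTruth,
    cvr_jitter: float = 0.0,
    cbf_jitter: float = 0.0,
    seed: int = 1,
) -> PhantomTruth:
    """Perturbed copy of the truth emulating between-visit variability.

    Each brain voxel's CVR (and CBF ratio) is multiplied by
    1 + jitter * z with z ~ N(0, 1), clipped to stay positive.  Zero
    jitter returns an identical truth (apart from the new seed).
    """
    if cvr_jitter < 0 or cbf_jitter < 0:
        raise ValueError("jitter magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    brain = truth.brain_mask
    cvr = truth.cvr_truth.copy()
    cbf = truth.cbf_ratio_truth.copy()
    if cvr_jitter > 0:
        factor = np.clip(1.0 + cvr_jitter * rng.standard_normal(brain.sum()), 0.05, None)
        cvr[brain] = cvr[brain] * factor
    if cbf_jitter > 0:
        factor = np.clip(1.0 + cbf_jitter * rng.standard_normal(brain.sum()), 0.05, None)
        excess = (cbf[brain] - 1.0) * factor
        cbf[brain] = 1.0 + np.clip(excess, 0.0, None)
    return replace(truth, cvr_truth=cvr, cbf_ratio_truth=cbf, seed=seed)
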