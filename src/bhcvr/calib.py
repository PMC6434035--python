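"""CVR maps and Davis-model calibration (the M parameter).

CVR is reported as the BH-evoked percent signal change: the GLM beta of the
unit-peak BH regressor divided by the voxel's baseline signal, times 100.
The Davis model links the BOLD change to flow and oxygen metabolism,

    dBOLD/BOLD0 = M * (1 - (CBF/CBF0)^(alpha-beta) * (CMRO2/CMRO2_0)^beta),

with alpha the flow-volume coupling exponent and beta the susceptibility
exponent.  During a hypercapnic challenge such as a breath-hold the CMRO2
ratio is taken as 1, so M — the maximum attainable BOLD signal change —
follows directly from the measured CVR and the CBF ratio:

    M = (dBOLD/BOLD0) / (1 - (CBF/CBF0)^(alpha-beta)).

The CBF ratio comes from the perfusion-weighted (PW) activation:
CBF/CBF0 = 1 + beta_PW / baseline_PW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DavisParams:
    """Davis-model constants.

    alpha: flow-volume coupling (dimensionless), default 0.2.
    beta: susceptibility exponent (dimensionless), default 1.0.
    cmro2_ratio: CMRO2/CMRO2_0 during the challenge; fixed at 1 for
    hypercapnia-like stimuli.
    """

    alpha: float = 0.2
    beta: float = 1.0
    cmro2_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha == self.beta:
            raise ValueError("alpha == beta makes the Davis model degenerate")
        if self.cmro2_ratio != 1.0:
            raise ValueError("this pipeline assumes CMRO2/CMRO2_0 = 1")


@dataclass
class CvrMMaps:
    """Per-session CVR (%), CBF ratio, and M (%) maps with validity mask."""

    cvr_pct: np.ndarray
    cbf_ratio: np.ndarray
    m_pct: np.ndarray
    valid_mask: np.ndarray


def cvr(beta_map: np.ndarray, baseline_map: np.ndarray) -> np.ndarray:
    """Percent signal change: 100 * beta / baseline.

    The BH regressor is unit-peak scaled, so beta is the peak response
    amplitude in signal units.  Voxels with non-positive baseline are NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * beta_map / baseline_map
    return np.where(baseline_map > 0, out, np.nan)


def cbf_ratio(pw_beta: np.ndarray, pw_baseline: np.ndarray) -> np.ndarray:
    """CBF/CBF0 during BH: 1 + beta_PW / baseline_PW.

    Voxels with non-positive PW baseline — typically white matter, where
    the perfusion signal vanishes and the ratio blows up — are NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 1.0 + pw_beta / pw_baseline
    return np.where(pw_baseline > 0, out, np.nan)


def m_map(
    cvr_pct: np.ndarray,
    cbf_ratio_map: np.ndarray,
    params: DavisParams | None = None,
) -> np.ndarray:
    """Davis M in percent: (CVR/100) / (1 - ratio^(alpha-beta)) * 100.

    NaN where the CBF ratio is undefined, non-positive, or exactly 1 (the
    denominator vanishes).
    """
    params = params or DavisParams()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 1.0 - cbf_ratio_map ** (params.alpha - params.beta)
        out = cvr_pct / denom
    bad = ~np.isfinite(cbf_ratio_map) | (cbf_ratio_map <= 0) | (denom == 0)
    return np.where(bad, np.nan, out)


def baseline_map(
    cleaned_4d: np.ndarray,
    paradigm=None,
    mode: str = "mean",
) -> np.ndarray:
    """Voxelwise baseline signal for percent-change normalization.

    mode="mean": full-series mean after nuisance removal (default).
    mode="paced": mean over paced-breathing frames only (frames outside
    breath-hold and recovery intervals), requiring a paradigm.
    """
    if mode == "mean":
        return cleaned_4d.mean(axis=-1)
    if mode == "paced":
        if paradigm is None:
            raise ValueError('mode="paced" requires a paradigm')
        t = paradigm.frame_times_s()
        in_task = np.zeros(len(t), dtype=bool)
        for onset in paradigm.bh_onsets_s():
            in_task |= (t >= onset) & (t < onset + paradigm.bh_s + paradigm.recovery_s)
        return cleaned_4d[..., ~in_task].mean(axis=-1)
    raise ValueError(f"unknown baseline mode {mode!r}")


def gm_wm_contrast(map_3d: np.ndarray, gm_mask: np.ndarray, wm_mask: np.ndarray) -> float:
    """Gray/white specificity proxy: mean over GM divided by mean over WM.

    NaN voxels (invalid fits) are excluded from both means.
    """
    if not gm_mask.any() or not wm_mask.any():
        raise ValueError("GM and WM masks must both be nonempty")
    gm_mean = np.nanmean(map_3d[gm_mask])
    wm_mean = np.nanmean(map_3d[wm_mask])
    if wm_mean == 0 or np.isnan(wm_mean):
        raise ValueError(f"white-matter mean is {wm_mean}; contrast undefined")
    return float(gm_mean / wm_mean)
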