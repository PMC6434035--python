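"""Test-retest repeatability metrics for paired-session maps.

Covers the Dice overlap of thresholded activation masks,

    D = 2|A1 ∩ A2| / (|A1| + |A2|),

a voxelwise repeatability index based on the normalized absolute difference,

    Repeatability = 1 - (1/N) * sum_i |x_i^TP1 - x_i^TP2| / (x_i^TP1 + x_i^TP2),

the two-way mixed-effects single-measurement intraclass correlation
ICC(3,1) = (BMS - EMS) / (BMS + (k-1)·EMS) from the subject-by-session
ANOVA, Fisher-z-transformed spatial correlation between sessions, and the
fraction of gray-matter voxels whose ICC clears conventional reliability
cutoffs (0.4 "fair", 0.6 "good").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class RetestReport:
    """Paired-session repeatability summary for one map variant."""

    dice: float
    repeatability: float
    repeatability_n_excluded: int
    pearson_r: float
    fisher_z: float
    overlap_mask: np.ndarray
    icc_gm_mean: float = np.nan
    icc_frac_04: float = np.nan
    icc_frac_06: float = np.nan
    icc31_map: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def dice(mask_tp1: np.ndarray, mask_tp2: np.ndarray) -> float:
    """Dice overlap of two activation masks: 2|A1∩A2| / (|A1|+|A2|)."""
    if mask_tp1.shape != mask_tp2.shape:
        raise ValueError("masks must share a grid")
    a, b = int(mask_tp1.sum()), int(mask_tp2.sum())
    if a + b == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return float(2.0 * np.sum(mask_tp1 & mask_tp2) / (a + b))


def repeatability(
    map_tp1: np.ndarray,
    map_tp2: np.ndarray,
    mask: np.ndarray,
) -> tuple[float, int]:
    """Normalized-absolute-difference repeatability over mask voxels.

    Voxels where x1 + x2 == 0 (or either value is NaN) are excluded and
    counted; returns (index, n_excluded).
    """
    if map_tp1.shape != map_tp2.shape or map_tp1.shape != mask.shape:
        raise ValueError("maps and mask must share a grid")
    x1, x2 = map_tp1[mask], map_tp2[mask]
    denom = x1 + x2
    ok = np.isfinite(denom) & (denom != 0)
    n_excluded = int(len(x1) - ok.sum())
    if not ok.any():
        raise ValueError("all voxels excluded (zero or undefined x1 + x2)")
    index = 1.0 - np.mean(np.abs((x1[ok] - x2[ok]) / denom[ok]))
    return float(index), n_excluded


def icc31(values: np.ndarray) -> np.ndarray:
    """ICC(3,1) from a subjects-by-sessions table (vectorized over voxels).

    ``values`` has shape (..., n_subjects, k_sessions); a two-way mixed
    ANOVA (subjects random, sessions fixed) gives between-subject (BMS) and
    error (EMS) mean squares, and

        ICC(3,1) = (BMS - EMS) / (BMS + (k-1)·EMS).

    The table must be complete (balanced design, no NaN cells); apply
    listwise deletion before calling.  Voxels with zero total variance
    return NaN.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape[-2:]
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
    grand = values.mean(axis=(-2, -1), keepdims=True)
    subj = values.mean(axis=-1, keepdims=True)
    sess = values.mean(axis=-2, keepdims=True)
    ss_subj = k * np.sum((subj - grand) ** 2, axis=(-2, -1))
    ss_sess = n * np.sum((sess - grand) ** 2, axis=(-2, -1))
    ss_tot = np.sum((values - grand) ** 2, axis=(-2, -1))
    ss_err = ss_tot - ss_subj - ss_sess
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (bms - ems) / (bms + (k - 1) * ems)
    return np.where(ss_tot > 0, icc, np.nan)


def spatial_correlation(
    map_tp1: np.ndarray,
    map_tp2: np.ndarray,
    mask: np.ndarray,
) -> tuple[float, float]:
    """Pearson r across mask voxels and its Fisher z = atanh(r).

    |r| = 1 yields an infinite z (flagged by the inf, not an error).
    """
    x1, x2 = map_tp1[mask], map_tp2[mask]
    ok = np.isfinite(x1) & np.isfinite(x2)
    x1, x2 = x1[ok], x2[ok]
    if len(x1) < 3:
        raise ValueError("need at least 3 voxels for a spatial correlation")
    if np.std(x1) == 0 or np.std(x2) == 0:
        raise ValueError("zero variance in one of the maps")
    r = float(stats.pearsonr(x1, x2).statistic)
    if 1.0 - abs(r) < 1e-12:  # affinely dependent maps: z diverges
        return r, float(np.sign(r) * np.inf)
    return r, float(np.arctanh(r))


def icc_fractions(
    icc_map: np.ndarray,
    gm_mask: np.ndarray,
    thresholds: tuple[float, ...] = (0.4, 0.6),
) -> tuple[float, ...]:
    """Fraction of GM voxels with a defined ICC above each threshold."""
    if not gm_mask.any():
        raise ValueError("gray-matter mask is empty")
    vals = icc_map[gm_mask]
    n = len(vals)
    return tuple(float(np.sum(vals > thr) / n) for thr in thresholds)


def overlap_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxels active at both time points (set intersection)."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a grid")
    return mask_a & mask_b


def extract_stats(t_map: np.ndarray, masks: dict[str, np.ndarray]) -> dict[str, float]:
    """Mean t within each named mask; empty masks yield NaN."""
    out = {}
    for name, m in masks.items():
        out[name] = float(np.nanmean(t_map[m])) if m.any() else np.nan
    return out
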