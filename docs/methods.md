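# Methods

This note records the model the package implements, the choices made where
the design was genuinely open, and what the synthetic phantom does and does
not establish about real data.

## Task schedule and regressors

The encoded breath-hold (BH) protocol is 44 s of paced breathing, four
cycles of (16 s end-expiration hold, 16 s recovery, 24 s paced breathing),
and a 24 s paced tail; the scanner prepends 64 s of calibration frames that
are discarded, so the analysed run is 292 s = 73 frames at TR = 4 s. The
model clock starts at the first retained frame: the convolution does not
treat the calibration period as signal history, since those frames carry no
task.

The BH regressor is the task boxcar convolved with a canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions, undershoot
ratio 1/6, 32-s support — exposed in `HrfParams`). Convolution runs on a
0.1-s grid (which divides every block duration) with zero padding, is
scaled to unit peak, then shifted and sampled at frame times. Shifts span
−2·TR … +8·TR in TR steps (11 regressors); shifted responses extending past
the scan are truncated, not wrapped, since wrap-around has no physiological
meaning. Note a fine point: the convolved response to a 16-s block peaks
essentially *at* the block's end (within half a second before it), where
the HRF's positive lobe crosses zero — the common intuition that the peak
strictly lags the block end holds only approximately on this schedule.

## Echo combination

T2* is fit voxelwise by unweighted ordinary least squares of ln(mean
signal) on echo time — the plain log-linear estimator, with a nonlinear
refit used only as a test oracle. Fits outside 2–300 ms, or voxels with a
non-positive mean at any echo, are flagged invalid rather than raising;
invalid voxels get uniform weights. Weights follow
w ∝ TE·e^(−TE/T2\*), normalized per voxel, and are computed per session
from that session's own data. The fit runs on cleaned (label/control
regressed, detrended) but **unsmoothed** echoes; smoothing is applied
afterwards to the analysis datasets, so the decay estimate is not
contaminated by cross-tissue mixing.

## Perfusion-weighted series

The PW series is the raw first echo (alternation intact) high-pass filtered
above 0.09 Hz and demodulated by (−1)ⁿ. The filter is a zero-phase
forward–backward Butterworth of order 4 with reflection padding: only the
cutoff is a protocol constant; the zero-phase choice avoids introducing lag
bias into the PW GLM. Label parity defaults to even frames = control and is
configurable; the sign convention makes baseline PW positive in gray
matter.

One consequence of the 0.09 Hz cutoff at TR = 4 s (Nyquist 0.125 Hz)
deserves emphasis: BH-response harmonics whose mirrored (pre-demodulation)
frequencies fall below the cutoff are removed from the data, so fitting the
*unfiltered* BH regressor to the filtered PW series underestimates the
response by roughly 15% on this schedule. The PW GLM therefore uses
regressors passed through the identical high-pass + demodulation operator
(`pw_filtered_bank`), matching the model to the measurement chain; with
this, the CBF ratio recovers the phantom truth to within a few percent. The
PW design contains only an intercept besides the regressor — the series is
already filtered, and perfusion noise is treated as temporally white (no
prewhitening).

## GLM and lag selection

BOLD designs contain an intercept, Legendre trends to order 3, the ±1
label/control alternation, and one lag-shifted BH regressor; each shift is
fit independently and the highest positive t wins, ties broken toward the
smaller (earlier, physiologically more plausible) shift. If no shift gives
t > 0 the maximal-t fit is kept with the lag flagged unreliable. The
threshold is one-sided (p < 0.001 by default), consistent with maximizing
the positive t. Residual degrees of freedom are reported as n − p for the
chosen design, uncorrected for the selection over 11 shifts; the resulting
anti-conservatism of the per-voxel null is real, deliberate (it mirrors
standard practice for this analysis), and measured rather than corrected —
the acceptance suite demonstrates the lag-swept null's false-positive rate
at p = 0.001 is several times nominal while the single-regressor null is
calibrated.

Prewhitening, when enabled, estimates the lag-1 autocorrelation of the OLS
residuals per voxel, applies the first-order small-sample bias correction
ρ ← ρ + (1+3ρ)/n (the raw estimator is biased low enough at n = 73 to
leave the whitened test visibly anti-conservative), clamps to |ρ| ≤ 0.99,
whitens series and design (first observation scaled by √(1−ρ²)), and
refits. Under ρ = 0.4 AR(1) noise this restores the empirical type-I error
at nominal 0.05 to ≈ 0.065, versus ≈ 0.11 unwhitened. A full ARMA(1,1)
restricted-maximum-likelihood noise model is out of scope; AR(1) captures
the leading effect.

## CVR, CBF ratio, and M

Baselines for percent change are the voxel's full-series mean after
nuisance removal (an alternative paced-breathing-frames-only baseline is
available by flag). Because the mean includes the activation itself, this
convention biases CVR low by ≈ CVR × (mean regressor) ≈ 0.3% relative — an
inherent property of the definition, shared by any implementation using it.
CVR = 100·β/baseline with the regressor at unit peak; the CBF ratio is
1 + β_PW/baseline_PW with non-positive PW baselines flagged invalid (this
is what excludes white matter, where the perfusion signal vanishes and the
ratio would blow up); M follows the Davis relation with α = 0.2, β = 1 and
a CMRO₂ ratio of 1, reported in percent. Invalid voxels propagate as NaN
and are excluded from all means. M and CVR are computed per session and
never pooled before the retest metrics.

## Retest metrics

Dice uses the p < 0.001 uncorrected activation masks (the threshold is a
flag, since Dice is threshold-dependent). The repeatability index excludes
voxels with x₁+x₂ = 0 (it is undefined there) and reports the exclusion
count. ICC(3,1) is computed in closed form from the balanced two-way ANOVA
decomposition, (BMS − EMS)/(BMS + (k−1)·EMS), vectorized over voxels —
equivalent to a mixed-model fit for balanced complete designs, which the
phantom guarantees; tests cross-check it against an independent ANOVA
oracle and `pingouin.intraclass_corr`. The default mask for map metrics is
gray matter, with a whole-brain option.

## The phantom

The generator renders known truth maps through the forward model

S_e(n) = S₀(n)·e^(−TE_e/T2\*)·e^(−TE_e·ΔR2\*(n)) + ε, with
ΔR2\*(n) = −ln(1+CVR)/TE_ref · reg(n) and
S₀(n) = S̄₀ + A·(−1)ⁿ·(1 + (CBF/CBF₀ − 1)·reg(n)),

so the BOLD effect is a rate change (percent amplitude grows with TE) and
the perfusion alternation rides on S₀ (decays with TE, dominating echo 1 —
its demodulated echo-1 amplitude is A·e^(−TE₁/T2\*), not A itself).
Geometry is a 12×12×8 grid with a WM core inside a GM ring; response lags
sweep all 11 shifts in contiguous diagonal bands, so every lag is exercised
while neighbours keep similar delays, as in real vascular territories.

Defaults (all config-exposed): GM CVR 1.7% at TE 25 ms, WM at half; GM
CBF ratio 1.5, WM 1.25; S̄₀ 1000/900; perfusion alternation 10/4 signal
units (~1% of S̄₀); white noise σ = 5 (unsmoothed echo-2 tSNR ≈ 75, typical
of single-echo BOLD at this resolution), with an optional AR(1) coefficient.
Effective T2\* defaults are 25 ms (GM) and 22 ms (WM): deliberately below
single-voxel tissue T2\* at 3 T, because the mono-exponential log-linear fit
to whole-tissue EPI magnitude absorbs macroscopic field-inhomogeneity
dephasing. This choice also places the signal-weighted effective echo time
of the T2\*-weighted combination below the second echo, reproducing the
in-vivo observation that combined-echo CVR is *lower* than second-echo CVR;
with effective T2\* above ≈ 30 ms the same weighting arithmetic flips the
direction, so the effective-decay regime is the one this phantom emulates.

What the phantom does **not** contain: motion, reconstruction artefacts,
slice timing, cardiac/respiratory physiology, spatial heterogeneity of CVR
within a tissue class, hypoxic BOLD dips during holds, or subject
non-compliance. Passing recovery tests therefore establishes correctness of
the estimator chain under the stated signal model, not robustness to
everything real data contains.

## Problem sizes and numerical choices

Parameter-recovery checks run the noiseless phantom without smoothing
(spatial smoothing deliberately mixes neighbouring truths — GM with WM, and
adjacent lag bands — which is a property of smoothing, not of the
estimators); noise-robustness checks run the default pipeline at echo-2
SNR 100. GLM calibration uses 10⁵ simulated null voxels (2×10⁴ for the
AR(1) case) at the protocol's 73 frames; the multi-subject retest study
uses 8 phantom subjects × 2 sessions with 20%/15% between-subject CVR/CBF
spread and 5% between-session jitter. Noiseless fits are flagged (t = ±inf,
r² = 1) via a residual-to-data sum-of-squares ratio below 10⁻¹⁸;
determinism is by construction — one `numpy` generator seeded per phantom,
no other randomness anywhere in the pipeline.

## Known limitations

* The lag grid equals the TR; true lags off the grid alias to the nearest
  shift (the phantom places truth on the grid, so this is untested).
* The label/control alternation and its BH-modulated product term are only
  partially separable from the BOLD regressor in 73 frames; the residual
  crosstalk biases per-voxel CVR by up to ≈ ±2% relative at the default
  perfusion amplitude (GM means are unaffected to < 1%).
* ICC requires a balanced complete subjects × sessions table; listwise
  deletion is the caller's responsibility.
* The CLI's stage subcommands recompute the (deterministic, cheap) pipeline
  up to the requested stage rather than consuming intermediate files.
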