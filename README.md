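# bhcvr

Breath-hold cerebrovascular reactivity (CVR) analysis for multi-echo
simultaneous ASL/BOLD fMRI, with a synthetic multi-echo phantom so the whole
pipeline can be exercised and validated without scanner data.

## The problem

Cerebrovascular reactivity — the vascular response to a vasodilatory
stimulus — can be mapped with fMRI by having a subject perform timed
breath-holds: the CO₂ rise dilates vessels, raising cerebral blood flow and
the BOLD signal. A simultaneous multi-echo ASL/BOLD acquisition interleaves
pCASL label/control frames and reads out several gradient echoes per frame,
which lets one pipeline deliver, from a single scan:

* **echo-combined BOLD** with higher temporal SNR than any single echo,
* a **perfusion-weighted (PW)** time series from the shortest echo,
* **breath-hold activation** maps with voxelwise hemodynamic-lag
  optimization,
* **CVR** maps (percent signal change per breath-hold), and
* **Davis-model M** maps (the hypercapnic BOLD ceiling), plus
* **test–retest metrics** (Dice, repeatability, ICC(3,1)) for paired
  sessions.

This package is aimed at fMRI methods researchers who want a transparent,
testable reference implementation of that chain.

## The model

**Echo combination.** The time-averaged signal of each echo follows
S(TEₙ) = S̄₀·e^(−TEₙ/T2\*); a voxelwise log-linear fit gives S̄₀ and T2\*, and
the echoes are summed with weights

&nbsp;&nbsp;&nbsp;&nbsp;w(T2\*) = TEₙ·e^(−TEₙ/T2\*) / Σₙ TEₙ·e^(−TEₙ/T2\*),

which peak at the echo nearest T2\*, where BOLD contrast is maximal.

**Perfusion.** The pCASL alternation puts the perfusion signal at the
Nyquist frequency. High-pass filtering the first echo above 0.09 Hz and
demodulating by cos(πn) = (−1)ⁿ shifts it to baseband, yielding the PW
series (positive = control − label).

**Activation.** The breath-hold regressor is a boxcar (1 during holds)
convolved with a canonical double-gamma HRF. Because the BH response is slow
and its delay varies across the brain, the regressor is shifted from −2·TR
to +8·TR in steps of TR and, per voxel, the shift with the highest positive
t-score in the GLM wins. Nuisance columns: intercept, cubic Legendre trends,
and the ±1 label/control alternation (BOLD only). Optional AR(1)
prewhitening handles temporal autocorrelation.

**CVR and M.** CVR = 100·β/baseline, with β the unit-peak-regressor
amplitude and baseline the mean signal. With the CBF ratio from the PW data
(CBF/CBF₀ = 1 + β_PW/baseline_PW) the Davis model under hypercapnia
(CMRO₂/CMRO₂,₀ = 1, α = 0.2, β = 1) gives

&nbsp;&nbsp;&nbsp;&nbsp;M = (ΔBOLD/BOLD₀) / (1 − (CBF/CBF₀)^(α−β)).

**Retest.** Dice D = 2|A₁∩A₂|/(|A₁|+|A₂|) on p < 0.001 activation masks;
repeatability = 1 − mean|Δx/Σx| over gray matter; ICC(3,1) from the
subjects × sessions ANOVA; Fisher-z spatial correlation; fractions of GM
voxels with ICC above 0.4/0.6.

## Worked example

```python
import numpy as np
from bhcvr import build_paradigm, analyze_session, compare_sessions
from bhcvr.phantom import default_truth, generate_phantom, second_session

paradigm = build_paradigm()          # 356-s scan, 73 frames at TR = 4 s
truth = default_truth(seed=1)        # 12x12x8 phantom, GM ring / WM core
series = generate_phantom(truth, paradigm)

res = analyze_session(series, paradigm, truth.gm_mask, truth.wm_mask)
gm = truth.gm_mask
for name in ("E2", "MEC", "PW"):
    act = res.activation[name]
    print(f"{name:>3}: tSNR={np.nanmean(res.tsnr_map[name][gm]):6.1f}  "
          f"mean t={np.nanmean(act.tstat[gm]):5.2f}  "
          f"CVR={np.nanmean(res.cvr_pct[name][gm]):5.2f}%")
print(f"Davis M (MEC): {np.nanmean(res.m_pct['MEC'][gm]):.2f}%  "
      f"CBF/CBF0: {np.nanmean(res.cbf_ratio_map[gm]):.2f}")

truth2 = second_session(truth, cvr_jitter=0.05, cbf_jitter=0.05, seed=2)
res2 = analyze_session(generate_phantom(truth2, paradigm, seed=3),
                       paradigm, gm, truth.wm_mask)
rep = compare_sessions(res, res2, gm, truth.wm_mask)["cvr"]["MEC"]
print(f"retest (MEC CVR): Dice={rep.dice:.3f}  "
      f"repeatability={rep.repeatability:.3f}")
```

prints

```
 E2: tSNR= 194.9  mean t= 8.85  CVR= 1.56%
MEC: tSNR= 310.9  mean t=12.52  CVR= 1.38%
 PW: tSNR=   8.8  mean t=10.83  CVR=45.55%
Davis M (MEC): 5.46%  CBF/CBF0: 1.46
retest (MEC CVR): Dice=1.000  repeatability=0.964
```

Reading it: echo combination (MEC) raises tSNR and activation strength over
the single second echo (E2) while *lowering* mean CVR — the weighted sum
mixes in shorter echoes whose signal is higher but whose percent change is
smaller. The PW series is far noisier (tSNR ≈ 9), as perfusion data are.
The recovered CVR (1.56% vs a 1.7% ground truth in GM, attenuated by
GM/WM smoothing mixture), CBF ratio (1.46 vs 1.5) and M sit near the
phantom's injected physiology, and the paired-session metrics show the
near-ceiling repeatability expected at phantom SNR.

The same run is available from the shell:

```bash
bhcvr all -c examples/phantom.yaml --out bhcvr_out   # full pipeline
bhcvr simulate -c examples/phantom.yaml              # or stage by stage
```

writing per-stage NIfTI maps, `summary.tsv`, `retest.tsv` and a provenance
log (`run_log.json`) to the output directory.

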