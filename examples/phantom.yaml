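# Default two-session phantom run: simulate -> ... -> retest.
# All blocks are optional; omitted keys fall back to the protocol defaults
# (356-s schedule, TE = 9.1/25/39.6/54.3 ms, TR = 4 s, 4.5-mm smoothing,
# p < 0.001, Davis alpha = 0.2 / beta = 1).
output_dir: bhcvr_out
seed: 1

paradigm:
  lead_in_s: 44
  n_cycles: 4
  bh_s: 16
  recovery_s: 16
  paced_s: 24
  tail_s: 24
  calibration_s: 64
  tr_s: 4.0

phantom:
  shape: [12, 12, 8]
  noise_sd: 5.0
  two_sessions: true
  cvr_jitter: 0.05
  cbf_jitter: 0.05

processing:
  fwhm_mm: 4.5
  voxel_size_mm: 3.0
  p_thresh: 0.001
  alpha: 0.2
  beta: 1.0
  baseline_mode: mean
  cutoff_hz: 0.09
  filter_order: 4
  prewhiten: false
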