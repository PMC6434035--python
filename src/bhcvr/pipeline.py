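"""End-to-end orchestration: phantom/session analysis and retest comparison.

One session flows through: per-echo label/control regression and cubic
detrending -> voxelwise T2* fit and weighted echo combination -> three
analysis datasets (E2 = second echo alone, MEC = multi-echo combined,
PW = demodulated perfusion-weighted first echo) -> spatial smoothing ->
lag-swept breath-hold GLM per dataset -> CVR, CBF-ratio and Davis-M maps.
Two sessions feed the retest metrics (Dice, repeatability, spatial
correlation); reliability across a cohort of phantom "subjects" uses
:func:`bhcvr.retest.icc31` on stacked per-subject maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .calib import DavisParams, baseline_map, cbf_ratio, cvr, gm_wm_contrast, m_map
from .echoes import MultiEchoSeries, combine, compute_weights, fit_t2star, tsnr
from .glm import fraction_active, lag_sweep, nuisance_matrix, smooth
from .io import save_json, save_table, write_nifti
from .paradigm import Paradigm, build_paradigm, build_regressor_bank
from .perfusion import (
    detrend_poly,
    pw_filtered_bank,
    pw_from_echo1,
    regress_label_control,
)
from .phantom import PhantomTruth, default_truth, generate_phantom, second_session
from .retest import (
    RetestReport,
    dice,
    extract_stats,
    overlap_mask,
    repeatability,
    spatial_correlation,
)

log = logging.getLogger("bhcvr")

STAGES = (
    "simulate",
    "preprocess",
    "combine",
    "perfusion",
    "activate",
    "calibrate",
    "retest",
)

BOLD_VARIANTS = ("E2", "MEC")
VARIANTS = ("E2", "MEC", "PW")


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable analysis parameters with the study's defaults."""

    fwhm_mm: float = 4.5
    voxel_size_mm: float = 3.0
    detrend_order: int = 3
    p_thresh: float = 0.001
    alpha: float = 0.2
    beta: float = 1.0
    baseline_mode: str = "mean"
    cutoff_hz: float = 0.09
    filter_order: int = 4
    prewhiten: bool = False
    shifts_s: tuple | None = None

    @property
    def davis(self) -> DavisParams:
        return DavisParams(alpha=self.alpha, beta=self.beta)


@dataclass
class SessionResult:
    """Everything one session's analysis produces, keyed by dataset variant."""

    series: MultiEchoSeries
    cleaned: np.ndarray | None = None  # (E, x, y, z, t) after nuisance removal
    t2s: object = None
    weights: object = None
    datasets: dict = field(default_factory=dict)  # variant -> smoothed 4-D
    activation: dict = field(default_factory=dict)  # variant -> ActivationResult
    baseline: dict = field(default_factory=dict)  # variant -> 3-D map
    cvr_pct: dict = field(default_factory=dict)
    cbf_ratio_map: np.ndarray | None = None
    m_pct: dict = field(default_factory=dict)
    tsnr_map: dict = field(default_factory=dict)
    truth: PhantomTruth | None = None


def analyze_session(
    series: MultiEchoSeries,
    paradigm: Paradigm,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
    cfg: ProcessingConfig = ProcessingConfig(),
    upto: str = "calibrate",
) -> SessionResult:
    """Run one session through the pipeline, stopping after stage ``upto``."""
    stop = STAGES.index(upto)
    brain = gm_mask | wm_mask
    res = SessionResult(series=series)
    bank = build_regressor_bank(paradigm, shifts_s=cfg.shifts_s)

    # preprocess: remove label/control alternation and slow drifts per echo
    cleaned = np.stack(
        [
            detrend_poly(regress_label_control(series.echo(e)), cfg.detrend_order)
            for e in range(series.n_echoes)
        ]
    )
    res.cleaned = cleaned
    if stop < STAGES.index("combine"):
        return res

    # combine: T2* fit on the cleaned, unsmoothed echoes, then weighted sum
    cleaned_series = series.with_data(cleaned)
    res.t2s = fit_t2star(cleaned_series)
    res.weights = compute_weights(res.t2s, series.te_ms)
    mec = combine(cleaned_series, res.weights)
    e2 = cleaned[1]
    if stop < STAGES.index("perfusion"):
        res.datasets = {"E2": e2, "MEC": mec}
        return res

    # perfusion: PW series from the raw first echo (alternation intact)
    pw = pw_from_echo1(series, cfg.cutoff_hz, cfg.filter_order).data
    raw = {"E2": e2, "MEC": mec, "PW": pw}
    if stop < STAGES.index("activate"):
        res.datasets = raw
        return res

    # activate: smooth, then lag-swept GLM per dataset variant
    n = series.n_frames
    nuis = {
        "E2": nuisance_matrix(n, cfg.detrend_order, include_alternation=True),
        "MEC": nuisance_matrix(n, cfg.detrend_order, include_alternation=True),
        "PW": nuisance_matrix(n, 0, include_alternation=False),
    }
    # the PW data went through the high-pass + demodulation operator, so its
    # regressors must too (the BOLD bank rows stay raw)
    pw_bank = pw_filtered_bank(bank, series.tr_s, cfg.cutoff_hz, cfg.filter_order)
    for name, data in raw.items():
        sm = smooth(data, cfg.fwhm_mm, cfg.voxel_size_mm, mask=brain)
        res.datasets[name] = sm
        res.activation[name] = lag_sweep(
            sm,
            pw_bank if name == "PW" else bank,
            nuis[name],
            mask=brain,
            prewhiten=cfg.prewhiten and name != "PW",
            p_thresh=cfg.p_thresh,
        )
        res.tsnr_map[name] = tsnr(sm, res.activation[name].fitted)
    if stop < STAGES.index("calibrate"):
        return res

    # calibrate: CVR / CBF ratio / Davis M
    for name in VARIANTS:
        res.baseline[name] = baseline_map(
            res.datasets[name], paradigm, cfg.baseline_mode
        )
        res.cvr_pct[name] = cvr(res.activation[name].beta, res.baseline[name])
    res.cbf_ratio_map = cbf_ratio(res.activation["PW"].beta, res.baseline["PW"])
    for name in BOLD_VARIANTS:
        res.m_pct[name] = m_map(res.cvr_pct[name], res.cbf_ratio_map, cfg.davis)
    return res


def session_summary(
    res: SessionResult, gm_mask: np.ndarray, wm_mask: np.ndarray
) -> list[dict]:
    """Per-variant scalar summaries (tSNR, activation, CVR/M, GM/WM contrast)."""
    rows = []
    for name in VARIANTS:
        act = res.activation[name]
        row = {
            "variant": name,
            "tsnr_gm": float(np.nanmean(res.tsnr_map[name][gm_mask])),
            "tscore_gm": float(np.nanmean(act.tstat[gm_mask])),
            "fraction_active_gm": fraction_active(act.active_mask_p001, gm_mask),
            "variance_explained_gm": float(np.nanmean(act.r2[gm_mask])),
            "cvr_gm_pct": float(np.nanmean(res.cvr_pct[name][gm_mask])),
        }
        if name in BOLD_VARIANTS:
            row["m_gm_pct"] = float(np.nanmean(res.m_pct[name][gm_mask]))
            row["cvr_gm_wm_contrast"] = gm_wm_contrast(
                res.cvr_pct[name], gm_mask, wm_mask
            )
            row["m_gm_wm_contrast"] = gm_wm_contrast(res.m_pct[name], gm_mask, wm_mask)
        rows.append(row)
    return rows


def compare_sessions(
    res1: SessionResult,
    res2: SessionResult,
    gm_mask: np.ndarray,
    wm_mask: np.ndarray,
) -> dict[str, dict[str, RetestReport]]:
    """Paired-session retest metrics per variant.

    Returns {"cvr": {variant: report}, "m": {variant: report}} where the
    activation-mask metrics (Dice, overlap) live on the CVR entries.
    """
    out = {"cvr": {}, "m": {}}
    for name in VARIANTS:
        m1 = res1.activation[name].active_mask_p001
        m2 = res2.activation[name].active_mask_p001
        ov = overlap_mask(m1, m2)
        rep, nexc = repeatability(res1.cvr_pct[name], res2.cvr_pct[name], gm_mask)
        r, z = spatial_correlation(res1.cvr_pct[name], res2.cvr_pct[name], gm_mask)
        stats1 = extract_stats(res1.activation[name].tstat, {"gm": gm_mask, "overlap": ov})
        out["cvr"][name] = RetestReport(
            dice=dice(m1, m2),
            repeatability=rep,
            repeatability_n_excluded=nexc,
            pearson_r=r,
            fisher_z=z,
            overlap_mask=ov,
            extra={"tscore_gm_tp1": stats1["gm"], "tscore_overlap_tp1": stats1["overlap"]},
        )
        if name in BOLD_VARIANTS:
            rep, nexc = repeatability(res1.m_pct[name], res2.m_pct[name], gm_mask)
            r, z = spatial_correlation(res1.m_pct[name], res2.m_pct[name], gm_mask)
            out["m"][name] = RetestReport(
                dice=np.nan,
                repeatability=rep,
                repeatability_n_excluded=nexc,
                pearson_r=r,
                fisher_z=z,
                overlap_mask=ov,
            )
    return out


def _paradigm_from_config(cfg: dict) -> Paradigm:
    return build_paradigm(**cfg.get("paradigm", {}))


def _truth_from_config(cfg: dict, seed: int) -> PhantomTruth:
    ph = dict(cfg.get("phantom", {}))
    ph.pop("two_sessions", None)
    ph.pop("cvr_jitter", None)
    ph.pop("cbf_jitter", None)
    if "shape" in ph:
        ph["shape"] = tuple(ph["shape"])
    return default_truth(seed=seed, **ph)


def _processing_from_config(cfg: dict) -> ProcessingConfig:
    proc = dict(cfg.get("processing", {}))
    if proc.get("shifts_s") is not None:
        proc["shifts_s"] = tuple(proc["shifts_s"])
    known = {f.name for f in fields(ProcessingConfig)}
    bad = set(proc) - known
    if bad:
        raise ValueError(f"unknown processing keys: {sorted(bad)}")
    return ProcessingConfig(**proc)


def run_pipeline(config: dict, upto: str = "retest") -> dict:
    """Run the configured pipeline up to ``upto`` and write artifacts.

    The config mapping carries ``output_dir``, ``seed``, and optional
    ``paradigm``, ``phantom`` and ``processing`` blocks (phantom simulation
    is the default input source; external NIfTI inputs go through
    :mod:`bhcvr.io` and `analyze_session` directly).  Deterministic given
    the seed.  Returns a manifest of what was computed.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGES}")
    outdir = Path(config.get("output_dir", "bhcvr_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    paradigm = _paradigm_from_config(config)
    proc = _processing_from_config(config)
    ph_cfg = config.get("phantom", {})
    two_sessions = bool(ph_cfg.get("two_sessions", True)) and upto == "retest"
    # a second session only matters for the retest stage

    manifest = {
        "version": __version__,
        "seed": seed,
        "upto": upto,
        "paradigm": {
            "total_duration_s": paradigm.total_duration_s,
            "n_frames": paradigm.n_frames,
        },
        "processing": {f.name: getattr(proc, f.name) for f in fields(ProcessingConfig)},
        "outputs": [],
    }

    def save(path, data):
        write_nifti(outdir / path, data)
        manifest["outputs"].append(str(path))

    truth1 = _truth_from_config(config, seed=seed)
    truths = [truth1]
    if two_sessions:
        truths.append(
            second_session(
                truth1,
                cvr_jitter=float(ph_cfg.get("cvr_jitter", 0.05)),
                cbf_jitter=float(ph_cfg.get("cbf_jitter", 0.05)),
                seed=seed + 1,
            )
        )

    gm, wm = truth1.gm_mask, truth1.wm_mask
    save("gm_mask.nii", gm.astype(float))
    save("wm_mask.nii", wm.astype(float))

    results = []
    analysis_upto = "calibrate" if upto == "retest" else upto
    for k, truth in enumerate(truths, start=1):
        log.info("session %d: simulating phantom (seed %d)", k, truth.seed)
        series = generate_phantom(truth, paradigm)
        for e in range(series.n_echoes):
            save(f"session{k}/echo{e + 1}.nii", series.echo(e))
        save_json(
            outdir / f"session{k}/truth.json",
            {
                "seed": truth.seed,
                "noise_sd": truth.noise_sd,
                "te_ms": list(truth.te_ms),
                "lag_map_s": truth.lag_map_s,
                "cvr_truth": truth.cvr_truth,
                "cbf_ratio_truth": truth.cbf_ratio_truth,
            },
        )
        if upto == "simulate":
            continue
        log.info("session %d: analysing up to %s", k, analysis_upto)
        res = analyze_session(series, paradigm, gm, wm, proc, upto=analysis_upto)
        res.truth = truth
        results.append(res)
        _write_session(save, outdir, k, res, analysis_upto)

    if upto == "simulate":
        save_json(outdir / "run_log.json", manifest)
        return manifest

    if STAGES.index(upto) >= STAGES.index("calibrate"):
        rows = []
        for k, res in enumerate(results, start=1):
            for row in session_summary(res, gm, wm):
                rows.append({"session": k, **row})
        save_table(outdir / "summary.tsv", rows)
        manifest["outputs"].append("summary.tsv")

    if upto == "retest":
        if len(results) == 2:
            reports = compare_sessions(results[0], results[1], gm, wm)
            rows = []
            for metric, per_variant in reports.items():
                for name, rep in per_variant.items():
                    rows.append(
                        {
                            "metric": metric,
                            "variant": name,
                            "dice": rep.dice,
                            "repeatability": rep.repeatability,
                            "n_excluded": rep.repeatability_n_excluded,
                            "pearson_r": rep.pearson_r,
                            "fisher_z": rep.fisher_z,
                            **rep.extra,
                        }
                    )
                    if metric == "cvr":
                        save(f"overlap_{name}.nii", rep.overlap_mask.astype(float))
            save_table(outdir / "retest.tsv", rows)
            manifest["outputs"].append("retest.tsv")
        else:
            log.info("retest stage skipped: only one session configured")
            manifest["retest_skipped"] = True

    save_json(outdir / "run_log.json", manifest)
    return manifest


def _write_session(save, outdir, k, res: SessionResult, upto: str) -> None:
    stop = STAGES.index(upto)
    for e in range(res.cleaned.shape[0]):
        save(f"session{k}/cleaned_echo{e + 1}.nii", res.cleaned[e])
    if stop < STAGES.index("combine"):
        return
    save(f"session{k}/t2star_ms.nii", res.t2s.t2star_ms)
    save(f"session{k}/s0.nii", res.t2s.s0)
    for e in range(res.weights.w.shape[0]):
        save(f"session{k}/weight_echo{e + 1}.nii", res.weights.w[e])
    if "MEC" in res.datasets:
        save(f"session{k}/mec.nii", res.datasets["MEC"])
    if stop < STAGES.index("perfusion"):
        return
    if "PW" in res.datasets:
        save(f"session{k}/pw.nii", res.datasets["PW"])
    if stop < STAGES.index("activate"):
        return
    for name, act in res.activation.items():
        save(f"session{k}/{name}_beta.nii", act.beta)
        save(f"session{k}/{name}_tstat.nii", act.tstat)
        save(f"session{k}/{name}_lag_s.nii", act.lag_s)
        save(f"session{k}/{name}_r2.nii", act.r2)
        save(f"session{k}/{name}_active_p001.nii", act.active_mask_p001.astype(float))
        save(f"session{k}/{name}_tsnr.nii", res.tsnr_map[name])
    if stop < STAGES.index("calibrate"):
        return
    for name, m in res.cvr_pct.items():
        save(f"session{k}/{name}_cvr_pct.nii", m)
    save(f"session{k}/cbf_ratio.nii", res.cbf_ratio_map)
    for name, m in res.m_pct.items():
        save(f"session{k}/{name}_m_pct.nii", m)
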