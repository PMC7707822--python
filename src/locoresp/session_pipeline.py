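"""End-to-end session analysis and cross-animal aggregation.

``analyze_session`` runs one recording through the full chain:
EMG integration -> burst detection -> respiratory cycles on one side;
pose cleaning -> stance/swing segmentation -> gait classification ->
stable-epoch selection on the other; then phase assignment, circular
statistics, orientation verdicts and cross-correlograms per reference
limb, restricted to stable epochs.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling_stats as cs
from . import emg_processing as emg_mod
from . import gait_kinematics as gk
from .errors import LocorespError, ParameterError
from .io_formats import (
    PoseTrack,
    SessionConfig,
    TimeSeries,
    write_result_tables,
)

logger = logging.getLogger("locoresp.pipeline")

#: analysis-parameter defaults, all overridable via SessionConfig.params
DEFAULT_PARAMS = {
    "integration_window": 0.015,
    "threshold_mode": "robust-baseline",
    "threshold": None,
    "k_mad": 5.0,
    "min_Ti": 0.02,
    # 5 ms rather than the bare-detector default 30 ms: at running breathing
    # rates (8-11 Hz) the true silent gap between bursts is ~15-20 ms, so a
    # 30 ms merge gap would fuse consecutive breaths.
    "merge_gap": 0.005,
    # 0.9 rather than the bare-detector default 0.5: the RMS envelope of a
    # noisy trace never falls to half the robust threshold, so a lower
    # hysteresis would let bursts run on indefinitely.
    "hysteresis_frac": 0.9,
    "baseline_epoch": None,      # [start, end] in s; default: first 5 s
    "run_epoch": None,           # default: whole overlap
    "window_s": 6.0,
    "n_windows": 3,
    "skip_s": 20.0,
    "likelihood_min": 0.9,
    "median_window_frames": 3,
    "vel_window": 0.01,
    "stance_frac": 0.25,
    "min_stance": 0.025,
    "min_swing": 0.025,
    "stable_win": 1.0,
    "stable_max_sd": 1.0,
    "stable_max_drift": 2.0,
    "gait_tol": 0.15,
    "context": "treadmill",
    "R_threshold": cs.R_THRESHOLD_DEFAULT,
    # whole-curve surrogate calibration needs record length >> n_lags/alpha,
    # so keep the lag window modest relative to a typical stable epoch
    "corr_max_lag": 0.5,
    "n_surrogates": 1000,
    "corr_alpha": 0.02,
    "seed": 0,
}

REFERENCE_LIMBS = ("rHL", "lHL", "rFL", "lFL")


@dataclass
class SessionResult:
    bursts: list = field(default_factory=list)
    resp_cycles: list = field(default_factory=list)
    stride_cycles: dict = field(default_factory=dict)    # limb -> [StrideCycle]
    epochs: list = field(default_factory=list)
    gait: gk.GaitLabel | None = None
    phases: dict = field(default_factory=dict)           # limb -> PhaseAssignment
    circ: dict = field(default_factory=dict)             # limb -> CircularStats
    verdicts: dict = field(default_factory=dict)         # limb -> OrientationVerdict
    correlograms: dict = field(default_factory=dict)     # limb -> Correlogram
    summary: emg_mod.MeasurementSummary | None = None
    amp_pct: float = float("nan")
    meta: dict = field(default_factory=dict)


@dataclass
class ConditionSummary:
    label: str
    n: int
    per_animal: dict = field(default_factory=dict)   # parameter -> [values]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)


@dataclass
class ComparisonResult:
    parameter: str
    U: float
    p: float
    mark: str


@contextmanager
def _stage(name: str):
    """Attach the failing stage's identity to any typed error it raises."""
    try:
        yield
    except LocorespError as exc:
        exc.stage = getattr(exc, "stage", name)
        exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
        raise


def _param(cfg: SessionConfig, key: str):
    return cfg.params.get(key, DEFAULT_PARAMS[key])


def _in_epochs(times: np.ndarray, epochs: list[gk.Epoch]) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for ep in epochs:
        mask |= (times >= ep.start) & (times < ep.end)
    return mask


def analyze_session(
    emg: TimeSeries, pose: dict[str, PoseTrack], cfg: SessionConfig
) -> SessionResult:
    """Analyze one session end-to-end; see module docstring for the chain."""
    result = SessionResult()

    # restrict to the overlap of the two recordings
    any_track = next(iter(pose.values()))
    pose_dur = any_track.n_frames / any_track.fps
    overlap = min(emg.duration, pose_dur)
    if overlap < emg.duration:
        emg = TimeSeries(emg.values[: int(round(overlap * emg.fs))], emg.fs, emg.t0)
    if overlap < pose_dur:
        n_keep = int(round(overlap * any_track.fps))
        pose = {
            bp: PoseTrack(bp, tr.x[:n_keep], tr.y[:n_keep],
                          tr.likelihood[:n_keep], tr.fps)
            for bp, tr in pose.items()
        }
    result.meta["analysis_duration"] = overlap

    # ----- respiratory chain -----
    with _stage("integrate_emg"):
        integrated = emg_mod.integrate_emg(emg, _param(cfg, "integration_window"))
    with _stage("detect_bursts"):
        det_cfg = emg_mod.BurstDetectConfig(
            integration_window=_param(cfg, "integration_window"),
            threshold_mode=_param(cfg, "threshold_mode"),
            threshold=_param(cfg, "threshold"),
            k_mad=_param(cfg, "k_mad"),
            min_Ti=_param(cfg, "min_Ti"),
            merge_gap=_param(cfg, "merge_gap"),
            hysteresis_frac=_param(cfg, "hysteresis_frac"),
        )
        baseline_epoch = _param(cfg, "baseline_epoch")
        if baseline_epoch is None:
            baseline_epoch = (0.0, min(5.0, overlap))
        result.bursts = emg_mod.detect_bursts(
            integrated, det_cfg, tuple(baseline_epoch)
        )
    with _stage("respiratory_cycles"):
        result.resp_cycles = emg_mod.respiratory_cycles(result.bursts)

    # ----- kinematic chain -----
    clean_cfg = gk.CleanConfig(
        likelihood_min=_param(cfg, "likelihood_min"),
        median_window_frames=_param(cfg, "median_window_frames"),
    )
    stance_cfg = gk.StanceConfig(
        belt_speed=cfg.belt_speed,
        vel_window=_param(cfg, "vel_window"),
        stance_frac=_param(cfg, "stance_frac"),
        min_stance=_param(cfg, "min_stance"),
        min_swing=_param(cfg, "min_swing"),
        v_ref=cfg.params.get("v_ref"),
    )
    cleaned: dict[str, PoseTrack] = {}
    with _stage("clean_pose"):
        for bp, tr in pose.items():
            cleaned[bp] = gk.clean_pose(tr, clean_cfg)
    with _stage("detect_stance_swing"):
        if cfg.belt_speed <= 0 and stance_cfg.v_ref is None:
            # stationary/rest recording: no reference speed, hence no strides
            logger.info("belt_speed = 0 and no v_ref configured: "
                        "skipping stride segmentation")
            result.stride_cycles = {limb: [] for limb in REFERENCE_LIMBS
                                    if limb in cleaned}
        else:
            for limb in REFERENCE_LIMBS:
                if limb in cleaned:
                    result.stride_cycles[limb] = gk.detect_stance_swing(
                        TimeSeries(cleaned[limb].x, fs=cleaned[limb].fps),
                        stance_cfg, limb=limb,
                    )
    with _stage("stable_epochs"):
        if "head" in cleaned:
            head = TimeSeries(cleaned["head"].x, fs=cleaned["head"].fps)
            result.epochs = gk.stable_epochs(
                head,
                gk.StableConfig(
                    win=_param(cfg, "stable_win"),
                    max_sd=_param(cfg, "stable_max_sd"),
                    max_drift=_param(cfg, "stable_max_drift"),
                ),
            )
    with _stage("classify_gait"):
        result.gait = _classify_from_strides(result.stride_cycles,
                                             _param(cfg, "gait_tol"))

    # ----- coupling statistics on stable epochs -----
    stable = [e for e in result.epochs if e.label == "stable"]
    onsets = np.array([b.onset for b in result.bursts])
    if stable:
        onsets = onsets[_in_epochs(onsets, stable)]
    with _stage("inspiration_phases"):
        for limb, strides in result.stride_cycles.items():
            strides_stable = [
                s for s in strides
                if not stable or _in_epochs(
                    np.array([s.footfall_prev]), stable)[0]
            ]
            if not strides_stable:
                result.phases[limb] = cs.PhaseAssignment()
                continue
            result.phases[limb] = cs.inspiration_phases(onsets, strides_stable)
    with _stage("circular_stats"):
        for limb, pa in result.phases.items():
            if not pa.samples:
                continue
            stats = cs.circular_stats(pa.phis())
            result.circ[limb] = stats
            result.verdicts[limb] = cs.orientation_verdict(
                stats,
                context=_param(cfg, "context"),
                R_threshold=_param(cfg, "R_threshold"),
            )
    with _stage("cross_correlogram"):
        result.correlograms = _correlograms(integrated, cleaned, stable, cfg)

    # ----- window-averaged respiratory summary -----
    with _stage("select_measurement_windows"):
        run_epoch = _param(cfg, "run_epoch")
        if run_epoch is None:
            run_epoch = (0.0, overlap)
        result.summary = emg_mod.select_measurement_windows(
            result.resp_cycles,
            tuple(run_epoch),
            emg_mod.WindowConfig(
                window_s=_param(cfg, "window_s"),
                n_windows=_param(cfg, "n_windows"),
                skip_s=_param(cfg, "skip_s"),
            ),
        )
        base_lo, base_hi = baseline_epoch
        baseline_cycles = [
            c for c in result.resp_cycles if base_lo <= c.onset < base_hi
        ]
        if baseline_cycles and np.isfinite(result.summary.amp_mean):
            base = float(np.mean([c.peak_amp for c in baseline_cycles]))
            result.amp_pct = cs.percent_of_baseline(result.summary.amp_mean, base)
    result.meta["n_bursts"] = len(result.bursts)
    result.meta["n_stable_epochs"] = len(stable)
    return result


def _classify_from_strides(stride_cycles: dict, tol: float) -> gk.GaitLabel:
    def footfalls(limb):
        return [s.footfall_prev for s in stride_cycles.get(limb, [])] + (
            [stride_cycles[limb][-1].footfall_next]
            if stride_cycles.get(limb) else []
        )

    try:
        hind = gk.relative_phase(footfalls("rHL"), footfalls("lHL"))
    except ParameterError:
        return gk.GaitLabel("undetermined", float("nan"), float("nan"))
    try:
        fore = gk.relative_phase(footfalls("rFL"), footfalls("lFL"))
    except ParameterError:
        fore = None
    return gk.classify_gait(hind, fore, tol=tol)


def _correlograms(
    integrated: TimeSeries,
    cleaned: dict[str, PoseTrack],
    stable: list[gk.Epoch],
    cfg: SessionConfig,
) -> dict:
    out: dict = {}
    if not stable:
        return out
    epoch = max(stable, key=lambda e: e.duration)
    max_lag = _param(cfg, "corr_max_lag")
    if epoch.duration < 4 * max_lag:
        max_lag = epoch.duration / 4 - 1.0 / cfg.fps
        if max_lag <= 0.1:
            logger.info("longest stable epoch too short for a correlogram")
            return out
    rng = np.random.default_rng(_param(cfg, "seed"))
    t_emg = integrated.times()
    for limb in REFERENCE_LIMBS:
        if limb not in cleaned:
            continue
        tr = cleaned[limb]
        i0 = int(np.ceil(epoch.start * tr.fps))
        i1 = int(np.floor(epoch.end * tr.fps))
        frames = np.arange(i0, i1)
        t_frames = frames / tr.fps
        env = np.interp(t_frames, t_emg, integrated.values)
        out[limb] = cs.cross_correlogram(
            TimeSeries(env, fs=tr.fps, t0=t_frames[0]),
            TimeSeries(tr.x[i0:i1], fs=tr.fps, t0=t_frames[0]),
            max_lag=max_lag,
            n_surrogates=_param(cfg, "n_surrogates"),
            alpha=_param(cfg, "corr_alpha"),
            rng=rng,
        )
    return out


# ---------------------------------------------------------------------------
# aggregation across animals and conditions
# ---------------------------------------------------------------------------

SUMMARY_PARAMETERS = ("freq", "Ti", "Te", "amp_pct")


def _animal_value(result: SessionResult, parameter: str) -> float:
    s = result.summary
    if s is None:
        return float("nan")
    return {
        "freq": s.f_mean, "Ti": s.Ti_mean, "Te": s.Te_mean,
        "amp_pct": result.amp_pct,
    }[parameter]


def summarize_condition(
    results: list[SessionResult], label: str
) -> ConditionSummary:
    """Group mean and sample SD (ddof 1) of per-animal window-averaged values."""
    if not results:
        raise ParameterError("summarize_condition requires at least one result")
    summary = ConditionSummary(label=label, n=len(results))
    for parameter in SUMMARY_PARAMETERS:
        vals = [
            v for v in (_animal_value(r, parameter) for r in results)
            if np.isfinite(v)
        ]
        summary.per_animal[parameter] = vals
        if not vals:
            summary.mean[parameter] = float("nan")
            summary.sd[parameter] = float("nan")
        else:
            summary.mean[parameter] = float(np.mean(vals))
            # single animal: SD of 0 flagged by n; ddof=1 otherwise
            summary.sd[parameter] = (
                0.0 if len(vals) == 1 else float(np.std(vals, ddof=1))
            )
    return summary


def compare_conditions(
    a: ConditionSummary, b: ConditionSummary, parameter: str
) -> ComparisonResult:
    if parameter not in a.per_animal or parameter not in b.per_animal:
        raise ParameterError(f"parameter '{parameter}' missing from a summary")
    va, vb = a.per_animal[parameter], b.per_animal[parameter]
    if not va or not vb:
        raise ParameterError(f"no per-animal values for '{parameter}'")
    res = cs.mann_whitney_u(va, vb)
    return ComparisonResult(
        parameter=parameter, U=res.U, p=res.p, mark=cs.significance_mark(res.p)
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_session_result(result: SessionResult, outdir: str | Path) -> None:
    """Write all result tables plus a one-row session summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_strides = [s for limb in REFERENCE_LIMBS
                   for s in result.stride_cycles.get(limb, [])]
    all_phases = [s for limb in REFERENCE_LIMBS
                  for s in result.phases.get(limb, cs.PhaseAssignment()).samples]
    write_result_tables(
        {
            "bursts": result.bursts,
            "resp_cycles": result.resp_cycles,
            "stride_cycles": all_strides,
            "epochs": result.epochs,
            "phases": all_phases,
        },
        outdir,
    )
    verdict_rows = []
    for limb in REFERENCE_LIMBS:
        if limb not in result.circ:
            continue
        st, vd = result.circ[limb], result.verdicts[limb]
        verdict_rows.append(
            dict(limb=limb, mean_phase=st.mean_phase, R=st.R, n=st.n,
                 oriented=vd.oriented, valid=vd.valid, context=vd.context)
        )
    pd.DataFrame(
        verdict_rows,
        columns=["limb", "mean_phase", "R", "n", "oriented", "valid", "context"],
    ).to_csv(outdir / "verdicts.csv", index=False, float_format="%.17g")
    s = result.summary
    gait = result.gait
    pd.DataFrame(
        [dict(
            freq=s.f_mean if s else np.nan,
            Ti=s.Ti_mean if s else np.nan,
            Te=s.Te_mean if s else np.nan,
            amp=s.amp_mean if s else np.nan,
            amp_pct=result.amp_pct,
            truncated=bool(s.truncated) if s else False,
            gait=gait.label if gait else "undetermined",
            hind_rel_phase=gait.hind_rel_phase if gait else np.nan,
            fore_rel_phase=gait.fore_rel_phase if gait else np.nan,
            duration=result.meta.get("analysis_duration", np.nan),
        )]
    ).to_csv(outdir / "summary.csv", index=False, float_format="%.17g")


def read_session_summary(outdir: str | Path) -> dict:
    df = pd.read_csv(Path(outdir) / "summary.csv")
    return df.iloc[0].to_dict()
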