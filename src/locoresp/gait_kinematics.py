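"""Gait kinematics from pose tracks.

Cleans pose tracks (likelihood gating, interpolation, running median),
segments each limb's forward motion into footfall-delimited stride cycles
via a velocity-threshold stance/swing detector, classifies trot vs gallop
from inter-limb relative phases, finds stable running epochs from the head
trace, and computes open-field mobility metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ValidationError
from .io_formats import PoseTrack, TimeSeries

logger = logging.getLogger("locoresp.gait")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StrideCycle:
    """One limb cycle between consecutive footfalls.

    Stance covers ``[footfall_prev, liftoff)``, swing ``[liftoff,
    footfall_next)``.
    """

    limb: str
    footfall_prev: float
    liftoff: float
    footfall_next: float

    def __post_init__(self) -> None:
        if not (self.footfall_prev < self.liftoff < self.footfall_next):
            raise ValidationError(
                f"stride ordering violated for limb '{self.limb}': "
                f"{self.footfall_prev} < {self.liftoff} < {self.footfall_next}"
            )

    @property
    def period(self) -> float:
        return self.footfall_next - self.footfall_prev

    @property
    def duty_factor(self) -> float:
        return (self.liftoff - self.footfall_prev) / self.period


@dataclass
class GaitLabel:
    label: str  # trot | gallop | undetermined
    hind_rel_phase: float
    fore_rel_phase: float


@dataclass
class Epoch:
    start: float
    end: float
    label: str  # stable | unstable

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(f"epoch end ({self.end}) <= start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CleanConfig:
    likelihood_min: float = 0.9
    median_window_frames: int = 3


@dataclass
class StanceConfig:
    """Velocity-threshold stance/swing detection parameters.

    ``belt_speed > 0`` selects the treadmill rule (stance = paw moving
    backward with the belt in the camera frame); otherwise ``v_ref`` (smoothed
    body speed) must be supplied and stance is near-zero world-frame velocity.
    """

    belt_speed: float = 0.0
    vel_window: float = 0.01
    stance_frac: float = 0.25
    min_stance: float = 0.025
    min_swing: float = 0.025
    v_ref: float | None = None


@dataclass
class StableConfig:
    win: float = 1.0
    max_sd: float = 1.0       # cm
    max_drift: float = 2.0    # cm/s


@dataclass
class OpenFieldConfig:
    mobility_speed: float = 7.5   # cm/s
    smooth_window_frames: int = 5


@dataclass
class OpenFieldMetrics:
    mobility_rate: float      # percent of time above the mobility threshold
    mobility_speed: float     # mean speed while mobile (nan when never mobile)
    distance: float           # total path length, cm
    mobility_defined: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def clean_pose(track: PoseTrack, cfg: CleanConfig | None = None) -> PoseTrack:
    """Interpolate low-likelihood frames, then apply a running median.

    Frames with likelihood below ``likelihood_min`` get x and y replaced by
    linear interpolation between the nearest valid neighbours; edge gaps hold
    the nearest valid value. The likelihood channel is left untouched.
    """
    cfg = cfg or CleanConfig()
    w = cfg.median_window_frames
    if w < 1 or w % 2 == 0:
        raise ParameterError(f"median_window_frames must be odd and >= 1, got {w}")
    valid = track.likelihood >= cfg.likelihood_min
    if not valid.any():
        raise ValidationError(
            f"track '{track.bodypart}': all {track.n_frames} frames below "
            f"likelihood {cfg.likelihood_min}"
        )
    idx = np.arange(track.n_frames)
    x = np.interp(idx, idx[valid], track.x[valid])
    y = np.interp(idx, idx[valid], track.y[valid])
    if w > 1:
        x = ndimage.median_filter(x, size=w, mode="nearest")
        y = ndimage.median_filter(y, size=w, mode="nearest")
    return replace(track, x=x, y=y)


def resample_track(track: PoseTrack, fs_target: float) -> tuple[TimeSeries, TimeSeries]:
    """Linearly interpolate x and y onto a uniform grid at ``fs_target``."""
    if fs_target < track.fps:
        raise ParameterError(
            f"fs_target ({fs_target} Hz) must be >= track fps ({track.fps} Hz)"
        )
    t_old = np.arange(track.n_frames) / track.fps
    duration = (track.n_frames - 1) / track.fps
    n_new = int(np.floor(duration * fs_target + 1e-9)) + 1
    t_new = np.arange(n_new) / fs_target
    x = np.interp(t_new, t_old, track.x)
    y = np.interp(t_new, t_old, track.y)
    return TimeSeries(x, fs=fs_target), TimeSeries(y, fs=fs_target)


def _moving_average(v: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return v
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.pad(v, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + v.size]
    return out


def _bool_runs(mask: np.ndarray) -> list[list[int]]:
    """Maximal runs of constant value: [start, end, value]."""
    n = mask.size
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [n]])
    return [[int(a), int(b), bool(mask[a])] for a, b in zip(bounds[:-1], bounds[1:])]


def _absorb_short_runs(mask: np.ndarray, min_true: int, min_false: int) -> np.ndarray:
    """Flip runs shorter than their minimum length, shortest first."""
    mask = mask.copy()
    while True:
        runs = _bool_runs(mask)
        if len(runs) <= 1:
            return mask
        offenders = [
            r for r in runs
            if (r[1] - r[0]) < (min_true if r[2] else min_false)
        ]
        if not offenders:
            return mask
        start, end, val = min(offenders, key=lambda r: r[1] - r[0])
        mask[start:end] = not val


_REFINE_FIT_SAMPLES = 4  # samples per side for sub-frame transition refinement


def detect_stance_swing(
    x: TimeSeries, cfg: StanceConfig, limb: str = ""
) -> list[StrideCycle]:
    """Segment a paw's forward-position trace into stride cycles.

    Forward velocity is estimated by central differences smoothed over
    ``vel_window``. On the treadmill, stance = maximal runs where velocity is
    below ``-stance_frac * belt_speed``; overground, stance = |velocity| below
    ``stance_frac * v_ref``. Runs shorter than ``min_stance``/``min_swing``
    are absorbed into their neighbours. Footfall = swing-to-stance transition.
    """
    fs = x.fs
    v = np.gradient(x.values) * fs
    n_smooth = max(1, int(round(cfg.vel_window * fs)))
    if n_smooth % 2 == 0:
        n_smooth += 1
    v = _moving_average(v, n_smooth)

    if cfg.belt_speed > 0:
        indicator = v - (-cfg.stance_frac * cfg.belt_speed)
    else:
        if cfg.v_ref is None or cfg.v_ref <= 0:
            raise ParameterError(
                "overground stance detection requires a positive v_ref "
                "(treadmill mode needs belt_speed > 0)"
            )
        indicator = np.abs(v) - cfg.stance_frac * cfg.v_ref
    stance = indicator < 0

    stance = _absorb_short_runs(
        stance,
        min_true=int(round(cfg.min_stance * fs)),
        min_false=int(round(cfg.min_swing * fs)),
    )

    def transition_time(a: int) -> float:
        # sub-frame refinement: the paw's forward position is piecewise
        # near-linear around a stance boundary (belt-driven in stance,
        # protraction in swing), so the transition is the intersection of
        # lines fitted just before and just after the boundary sample
        k = _REFINE_FIT_SAMPLES
        pre = slice(max(0, a - 1 - k), a - 1)
        post = slice(a + 1, min(x.n, a + 1 + k))
        n_pre, n_post = pre.stop - pre.start, post.stop - post.start
        if n_pre < 2 or n_post < 2:
            return x.t0 + a / fs
        i_pre = np.arange(pre.start, pre.stop)
        i_post = np.arange(post.start, post.stop)
        s1, b1 = np.polyfit(i_pre, x.values[pre], 1)
        s2, b2 = np.polyfit(i_post, x.values[post], 1)
        if s1 == s2:
            return x.t0 + a / fs
        cross = (b2 - b1) / (s1 - s2)
        cross = float(np.clip(cross, a - 2, a + 2))
        return x.t0 + cross / fs

    runs = _bool_runs(stance)
    # footfall = start of a stance run that follows swing (not record start)
    stance_runs = [(a, b) for a, b, val in runs if val and a > 0]
    if len(stance_runs) < 2:
        logger.info("limb '%s': fewer than 2 footfalls detected", limb)
        return []
    strides = []
    for (a, b), (a2, _) in zip(stance_runs[:-1], stance_runs[1:]):
        liftoff = transition_time(b) if b < x.n else x.t0 + b / fs
        strides.append(
            StrideCycle(
                limb=limb,
                footfall_prev=transition_time(a),
                liftoff=liftoff,
                footfall_next=transition_time(a2),
            )
        )
    return strides


def _phases_in_train(ref: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Phase of each event within its enclosing reference cycle, [0, 1)."""
    idx = np.searchsorted(ref, events, side="right") - 1
    ok = (idx >= 0) & (idx < ref.size - 1)
    idx = idx[ok]
    ev = events[ok]
    return (ev - ref[idx]) / (ref[idx + 1] - ref[idx])


def _circular_mean(phases: np.ndarray) -> float:
    z = np.exp(2j * np.pi * phases).mean()
    return float(np.angle(z) / (2 * np.pi) % 1.0)


def relative_phase(footfalls_a, footfalls_b) -> float:
    """Circular mean phase of B footfalls within A's stride cycles."""
    a = np.asarray(footfalls_a, dtype=float)
    b = np.asarray(footfalls_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ParameterError(
            f"relative_phase needs >= 3 footfalls per limb, got {a.size} and {b.size}"
        )
    phases = _phases_in_train(a, b)
    if phases.size == 0:
        raise ParameterError("no B footfalls fall inside A's stride cycles")
    return _circular_mean(phases)


def _circ_dist(p: float, q: float) -> float:
    d = abs(p - q) % 1.0
    return min(d, 1.0 - d)


def classify_gait(
    hind_rel_phase: float, fore_rel_phase: float | None = None, tol: float = 0.15
) -> GaitLabel:
    """Trot = alternating hindlimbs; gallop = synchronous hindlimbs with
    alternating forelimbs; anything else is undetermined."""
    fore = float("nan") if fore_rel_phase is None else fore_rel_phase
    if _circ_dist(hind_rel_phase, 0.5) <= tol:
        label = "trot"
    elif (
        _circ_dist(hind_rel_phase, 0.0) <= tol
        and fore_rel_phase is not None
        and _circ_dist(fore_rel_phase, 0.5) <= tol
    ):
        label = "gallop"
    else:
        label = "undetermined"
    return GaitLabel(label=label, hind_rel_phase=hind_rel_phase, fore_rel_phase=fore)


def stable_epochs(head_x: TimeSeries, cfg: StableConfig | None = None) -> list[Epoch]:
    """Stable running epochs from the head's horizontal trace.

    A sliding window is stable iff its SD is at most ``max_sd`` and the
    absolute slope of a linear fit is at most ``max_drift``; overlapping
    stable windows are merged into maximal epochs. Returns epochs (stable
    and unstable) tiling the whole record.
    """
    cfg = cfg or StableConfig()
    fs = head_x.fs
    n = head_x.n
    win_n = int(round(cfg.win * fs))
    t_end = head_x.t0 + head_x.duration
    if n < win_n or win_n < 2:
        logger.warning("head trace (%.2f s) shorter than window (%.2f s): "
                       "marking whole record unstable", head_x.duration, cfg.win)
        return [Epoch(head_x.t0, t_end, "unstable")]
    hop = max(1, win_n // 4)
    starts = list(range(0, n - win_n + 1, hop))
    if starts[-1] != n - win_n:
        starts.append(n - win_n)
    t_rel = (np.arange(win_n) - (win_n - 1) / 2) / fs
    denom = float((t_rel**2).sum())
    stable_mask = np.zeros(n, dtype=bool)
    for s in starts:
        seg = head_x.values[s:s + win_n]
        sd = seg.std()
        slope = float((t_rel * (seg - seg.mean())).sum() / denom)
        if sd <= cfg.max_sd and abs(slope) <= cfg.max_drift:
            stable_mask[s:s + win_n] = True
    epochs = []
    for a, b, val in _bool_runs(stable_mask):
        end = t_end if b == n else head_x.t0 + b / fs
        epochs.append(Epoch(head_x.t0 + a / fs, end, "stable" if val else "unstable"))
    return epochs


def open_field_metrics(
    x: np.ndarray,
    y: np.ndarray,
    fps: float,
    cfg: OpenFieldConfig | None = None,
) -> OpenFieldMetrics:
    """Mobility rate, mobility speed and travelled distance from a trajectory."""
    cfg = cfg or OpenFieldConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ParameterError("trajectory needs >= 2 frames with equal x/y lengths")
    disp = np.hypot(np.diff(x), np.diff(y))
    speed = _moving_average(disp * fps, cfg.smooth_window_frames)
    mobile = speed > cfg.mobility_speed
    rate = 100.0 * float(mobile.mean())
    if mobile.any():
        mob_speed = float(speed[mobile].mean())
        defined = True
    else:
        mob_speed = float("nan")
        defined = False
    return OpenFieldMetrics(
        mobility_rate=rate,
        mobility_speed=mob_speed,
        distance=float(disp.sum()),
        mobility_defined=defined,
    )
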