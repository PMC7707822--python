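"""Synthetic generator of coupled locomotor-respiratory sessions.

Produces limb pose tracks (periodic stride cycles with gait-specific
inter-limb phases, duty-cycled sawtooth paw trajectories in the treadmill
camera frame, tracking noise and likelihood dropouts) and a diaphragm EMG
trace whose inspiration onsets come from a refractory hazard process that
is either independent of the stride cycle (kappa = 0) or von-Mises
modulated around a preferred stride phase mu. All ground truth (footfalls,
liftoffs, inspiration onsets, true phases) is returned alongside, and the
whole session is fully determined by the scenario seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import i0 as bessel_i0

from .errors import ParameterError
from .io_formats import PoseTrack, TimeSeries

LIMBS = ("rHL", "lHL", "rFL", "lFL")

#: per-gait limb phase offsets within the common stride cycle
DEFAULT_OFFSETS = {
    # trot: diagonal pairs synchronous, homologous pairs alternating
    "trot": {"rHL": 0.0, "lFL": 0.0, "lHL": 0.5, "rFL": 0.5},
    # gallop: hindlimbs near-synchronous, forelimbs alternating
    "gallop": {"rHL": 0.0, "lHL": 0.05, "rFL": 0.5, "lFL": 0.95},
}

_REFRACTORY_FRAC = 0.6  # absolute refractory period as a fraction of 1/f_breath


@dataclass
class SimScenario:
    """Generative parameters for one synthetic session."""

    gait: str = "trot"
    stride_freq: float = 5.0      # Hz
    duty: float = 0.6
    belt_speed: float = 40.0      # cm/s
    f_breath_rest: float = 3.5    # Hz
    f_breath_run: float = 8.0     # Hz
    Ti_frac: float = 0.45         # burst duration as fraction of 1/f_breath
    cv_cycle: float = 0.03
    kappa: float = 0.0
    mu: float = 0.3
    ref_limb: str = "rHL"
    snr: float = 5.0
    fps: float = 200.0
    fs_emg: float = 2000.0
    duration: float = 60.0        # s
    dropout_rate: float = 0.02
    seed: int = 0
    rest_s: float = 0.0           # initial rest period (no locomotion, rest breathing)
    quiet_s: float = 0.0          # initial apnea (noise only): a quiet baseline epoch
    noise_cm: float = 0.02        # tracking noise SD
    head_drift_cmps: float = 0.0
    limb_offsets: dict | None = None

    def __post_init__(self) -> None:
        if self.gait not in ("trot", "gallop", "rest"):
            raise ParameterError(f"unknown gait '{self.gait}'")
        for name in ("stride_freq", "f_breath_rest", "f_breath_run",
                     "fps", "fs_emg", "duration"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if not (0 < self.duty < 1):
            raise ParameterError(f"duty must be in (0, 1), got {self.duty}")
        if not (0 < self.Ti_frac < _REFRACTORY_FRAC):
            raise ParameterError(
                f"Ti_frac must be in (0, {_REFRACTORY_FRAC}) so bursts end "
                f"within the refractory period, got {self.Ti_frac}"
            )
        if self.kappa < 0:
            raise ParameterError(f"kappa must be >= 0, got {self.kappa}")
        if not (0 <= self.mu < 1):
            raise ParameterError(f"mu must be in [0, 1), got {self.mu}")
        if self.snr < 0 or self.cv_cycle < 0 or self.rest_s < 0 or self.quiet_s < 0:
            raise ParameterError("snr, cv_cycle, rest_s and quiet_s must be >= 0")
        if not (0 <= self.dropout_rate <= 1):
            raise ParameterError("dropout_rate must be in [0, 1]")
        if self.ref_limb not in LIMBS:
            raise ParameterError(f"ref_limb must be one of {LIMBS}")
        if self.gait != "rest" and not self.belt_speed > 0:
            raise ParameterError("running gaits require belt_speed > 0")

    def offsets(self) -> dict[str, float]:
        if self.limb_offsets is not None:
            return dict(self.limb_offsets)
        return dict(DEFAULT_OFFSETS[self.gait]) if self.gait != "rest" else {}


@dataclass
class GroundTruth:
    footfalls: dict[str, np.ndarray] = field(default_factory=dict)
    liftoffs: dict[str, np.ndarray] = field(default_factory=dict)
    insp_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    insp_offsets: np.ndarray = field(default_factory=lambda: np.array([]))
    true_phases: np.ndarray = field(default_factory=lambda: np.array([]))


def scenario_from_yaml(path) -> SimScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimScenario)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown scenario keys: {sorted(unknown)}")
    return SimScenario(**raw)


def scenario_to_yaml(sc: SimScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(sc), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# gait generator
# ---------------------------------------------------------------------------

def _cycle_boundaries(sc: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Jittered stride-cycle boundary times of the common locomotor phase."""
    base = 1.0 / sc.stride_freq
    bounds = [sc.rest_s]
    while bounds[-1] < sc.duration + base:
        factor = max(1.0 + sc.cv_cycle * rng.standard_normal(), 0.2)
        bounds.append(bounds[-1] + base * factor)
    return np.asarray(bounds)


def simulate_gait(
    sc: SimScenario, rng: np.random.Generator | None = None
):
    """Generate pose tracks and locomotor ground truth.

    Returns ``(tracks, ground_truth, locomotor_phase)`` where
    ``locomotor_phase`` maps time to the (unwrapped) stride phase of the
    reference limb, or None for a rest scenario.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    n_frames = int(round(sc.duration * sc.fps))
    t = np.arange(n_frames) / sc.fps
    gt = GroundTruth()
    rest_positions = {"rHL": 3.0, "lHL": 3.3, "rFL": 8.0, "lFL": 8.3}

    if sc.gait == "rest":
        bounds = np.array([])
        offsets: dict[str, float] = {}
        phase_fn = None
    else:
        bounds = _cycle_boundaries(sc, rng)
        offsets = sc.offsets()
        knots = np.arange(bounds.size, dtype=float)
        off_ref = offsets[sc.ref_limb]

        def phase_fn(times, _b=bounds, _k=knots, _o=off_ref):
            return np.interp(times, _b, _k) - _o

    tracks: dict[str, PoseTrack] = {}
    for limb in LIMBS:
        x0 = rest_positions[limb]
        x = np.full(n_frames, x0)
        y = np.zeros(n_frames)
        if sc.gait != "rest":
            off = offsets[limb]
            k_max = bounds.size - 1
            targets = off + np.arange(int(np.ceil(k_max - off)) + 1)
            targets = targets[(targets >= 0) & (targets <= k_max)]
            ff = np.interp(targets, np.arange(bounds.size, dtype=float), bounds)
            lo_targets = targets + sc.duty
            lo_ok = lo_targets <= k_max
            lo = np.interp(lo_targets[lo_ok],
                           np.arange(bounds.size, dtype=float), bounds)
            gt.footfalls[limb] = ff
            gt.liftoffs[limb] = lo
            idx = np.searchsorted(ff, t, side="right") - 1
            for i in range(min(ff.size - 1, lo.size)):
                in_cycle = idx == i
                if not in_cycle.any():
                    continue
                tc = t[in_cycle]
                x_lo = x0 - sc.belt_speed * (lo[i] - ff[i])
                stance = tc < lo[i]
                xc = np.where(
                    stance,
                    x0 - sc.belt_speed * (tc - ff[i]),
                    x_lo + (x0 - x_lo) * (tc - lo[i]) / (ff[i + 1] - lo[i]),
                )
                yc = np.where(
                    stance, 0.0,
                    1.0 * np.sin(np.pi * np.clip(
                        (tc - lo[i]) / (ff[i + 1] - lo[i]), 0, 1)),
                )
                x[in_cycle] = xc
                y[in_cycle] = yc
        x = x + rng.normal(0.0, sc.noise_cm, n_frames)
        y = y + rng.normal(0.0, sc.noise_cm, n_frames)
        likelihood = rng.uniform(0.95, 1.0, n_frames)
        dropout = rng.random(n_frames) < sc.dropout_rate
        if dropout.any():
            nd = int(dropout.sum())
            likelihood[dropout] = rng.uniform(0.05, 0.45, nd)
            x[dropout] += rng.normal(0.0, 5.0, nd)
            y[dropout] += rng.normal(0.0, 5.0, nd)
        tracks[limb] = PoseTrack(limb, x, y, likelihood, sc.fps)

    head_x = (30.0 + sc.head_drift_cmps * t
              + rng.normal(0.0, sc.noise_cm, n_frames))
    head_y = 5.0 + rng.normal(0.0, sc.noise_cm, n_frames)
    tracks["head"] = PoseTrack(
        "head", head_x, head_y, rng.uniform(0.95, 1.0, n_frames), sc.fps
    )
    return tracks, gt, phase_fn


# ---------------------------------------------------------------------------
# breathing generator
# ---------------------------------------------------------------------------

def _draw_onsets(sc: SimScenario, locomotor_phase, rng) -> np.ndarray:
    """Inspiration onsets from a refractory, phase-modulated hazard process.

    After each onset comes an absolute refractory period of
    ``0.6 / f_breath``; the post-refractory hazard is
    ``lambda0 * exp(kappa * cos(2*pi*(phi(t) - mu))) / I0(kappa)`` with
    ``lambda0`` calibrated so the mean rate equals ``f_breath``
    (``kappa = 0`` gives a homogeneous process and uniform phases).
    """
    f_max = max(sc.f_breath_rest, sc.f_breath_run)
    i0k = float(bessel_i0(sc.kappa))
    lam_max = f_max / (1.0 - _REFRACTORY_FRAC) * np.exp(sc.kappa) / i0k

    def f_at(time: float) -> float:
        if sc.gait == "rest" or time < sc.rest_s:
            return sc.f_breath_rest
        return sc.f_breath_run

    def hazard(time: float) -> float:
        lam0 = f_at(time) / (1.0 - _REFRACTORY_FRAC)
        if sc.kappa == 0 or locomotor_phase is None or time < sc.rest_s:
            return lam0
        phi = float(locomotor_phase(time)) % 1.0
        return lam0 * np.exp(sc.kappa * np.cos(2 * np.pi * (phi - sc.mu))) / i0k

    onsets = []
    t = sc.quiet_s
    while True:
        # thinning over the post-refractory homogeneous proposal process
        t += rng.exponential(1.0 / lam_max)
        if t >= sc.duration:
            break
        if rng.random() < hazard(t) / lam_max:
            Ti = sc.Ti_frac / f_at(t)
            if t + Ti > sc.duration:
                break
            onsets.append(t)
            t += _REFRACTORY_FRAC / f_at(t)
    return np.asarray(onsets)


def simulate_breathing(
    sc: SimScenario,
    locomotor_phase=None,
    rng: np.random.Generator | None = None,
) -> tuple[TimeSeries, np.ndarray, np.ndarray]:
    """Generate the raw EMG trace; returns (emg, onsets, offsets).

    Each inspiration emits a burst of duration ``Ti_frac / f_breath``: a
    white-noise carrier under a linear rise over 80% of Ti followed by a
    sharp release, with amplitude ``snr`` times the baseline noise SD.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    onsets = _draw_onsets(sc, locomotor_phase, rng)
    n = int(round(sc.duration * sc.fs_emg))
    values = rng.normal(0.0, 1.0, n)
    offsets = []
    for onset in onsets:
        f = (sc.f_breath_rest if (sc.gait == "rest" or onset < sc.rest_s)
             else sc.f_breath_run)
        Ti = sc.Ti_frac / f
        i0 = int(round(onset * sc.fs_emg))
        i1 = min(n, int(round((onset + Ti) * sc.fs_emg)))
        m = i1 - i0
        if m <= 0:
            continue
        rel = np.arange(m) / (Ti * sc.fs_emg)
        env = np.clip(rel / 0.8, 0.0, 1.0)  # ramp up 80% of Ti, then plateau
        values[i0:i1] += env * sc.snr * rng.normal(0.0, 1.0, m)
        offsets.append(onset + Ti)
    return TimeSeries(values, fs=sc.fs_emg), onsets, np.asarray(offsets)


def _phases_from_footfalls(onsets: np.ndarray, ff: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(ff, onsets, side="right") - 1
    ok = (idx >= 0) & (idx < ff.size - 1)
    idx = idx[ok]
    return (onsets[ok] - ff[idx]) / (ff[idx + 1] - ff[idx])


def simulate_session(
    sc: SimScenario,
) -> tuple[TimeSeries, dict[str, PoseTrack], GroundTruth]:
    """Compose the gait and breathing generators on a common clock."""
    rng = np.random.default_rng(sc.seed)
    tracks, gt, phase_fn = simulate_gait(sc, rng)
    emg, onsets, offs = simulate_breathing(sc, phase_fn, rng)
    gt.insp_onsets = onsets
    gt.insp_offsets = offs
    if sc.gait != "rest" and sc.ref_limb in gt.footfalls:
        gt.true_phases = _phases_from_footfalls(onsets, gt.footfalls[sc.ref_limb])
    return emg, tracks, gt
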