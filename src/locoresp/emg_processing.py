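"""Diaphragm EMG processing.

Raw trace -> integrated activity (centered moving RMS) -> inspiratory
bursts (threshold search with hysteresis, merging and minimum duration)
-> per-cycle respiratory parameters (Ti, Te, instantaneous frequency,
peak amplitude) and window-averaged summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .io_formats import TimeSeries

logger = logging.getLogger("locoresp.emg")


@dataclass
class BurstEvent:
    """One bout of diaphragm activity (an inspiration)."""

    onset: float
    offset: float
    peak_amp: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValidationError(
                f"burst offset ({self.offset}) must exceed onset ({self.onset})"
            )
        if not self.peak_amp > 0:
            raise ValidationError(f"burst peak_amp must be > 0, got {self.peak_amp}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class RespCycle:
    """One respiratory cycle: a burst (Ti) plus the following silence (Te)."""

    onset: float
    Ti: float
    Te: float
    f_inst: float
    peak_amp: float

    def __post_init__(self) -> None:
        if not self.Ti > 0:
            raise ValidationError(f"Ti must be > 0, got {self.Ti}")
        if not self.Te > 0:
            raise ValidationError(f"Te must be > 0, got {self.Te}")
        if abs(self.f_inst - 1.0 / (self.Ti + self.Te)) >= 1e-9:
            raise ValidationError("f_inst inconsistent with 1/(Ti+Te)")


@dataclass
class BurstDetectConfig:
    """Parameters of the threshold burst search.

    ``threshold_mode`` is either ``"absolute"`` (use ``threshold`` directly)
    or ``"robust-baseline"`` (median + k_mad * MAD over a baseline epoch).
    A burst starts when the integrated signal reaches the upper threshold
    and ends when it falls below ``hysteresis_frac`` times the upper one.
    """

    integration_window: float = 0.015
    threshold_mode: str = "robust-baseline"
    threshold: float | None = None
    k_mad: float = 5.0
    min_Ti: float = 0.02
    merge_gap: float = 0.03
    hysteresis_frac: float = 0.5

    def __post_init__(self) -> None:
        if not self.integration_window > 0:
            raise ParameterError("integration_window must be > 0")
        if self.min_Ti < 0 or self.merge_gap < 0:
            raise ParameterError("min_Ti and merge_gap must be >= 0")
        if not (0 < self.hysteresis_frac <= 1):
            raise ParameterError("hysteresis_frac must be in (0, 1]")
        if self.threshold_mode not in ("absolute", "robust-baseline"):
            raise ParameterError(f"unknown threshold_mode '{self.threshold_mode}'")
        if self.threshold_mode == "absolute" and self.threshold is None:
            raise ParameterError("absolute threshold_mode requires a threshold value")


def integrate_emg(raw: TimeSeries, window: float = 0.015) -> TimeSeries:
    """Centered moving root-mean-square of the raw trace.

    The effective window is ``2h + 1`` samples with ``h = round(window*fs)//2``;
    near the edges the window shrinks symmetrically so the output has the same
    length and sampling rate as the input.
    """
    n_win = int(round(window * raw.fs))
    if n_win < 2:
        raise ParameterError(
            f"integration window ({window} s) must span at least 2 samples at "
            f"{raw.fs} Hz"
        )
    h = n_win // 2
    n = raw.n
    sq = raw.values**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    i = np.arange(n)
    hi = np.minimum(h, np.minimum(i, n - 1 - i))
    counts = 2 * hi + 1
    sums = csum[i + hi + 1] - csum[i - hi]
    return TimeSeries(np.sqrt(sums / counts), fs=raw.fs, t0=raw.t0)


def _robust_threshold(
    integrated: TimeSeries, cfg: BurstDetectConfig, baseline_epoch
) -> float:
    if baseline_epoch is None:
        raise ParameterError("robust-baseline threshold_mode requires a baseline_epoch")
    try:
        base = integrated.slice(*baseline_epoch)
    except ParameterError as exc:
        raise ParameterError(f"baseline_epoch is empty: {exc}") from exc
    med = float(np.median(base.values))
    mad = float(np.median(np.abs(base.values - med)))
    return med + cfg.k_mad * mad


def detect_bursts(
    integrated: TimeSeries,
    cfg: BurstDetectConfig,
    baseline_epoch: tuple[float, float] | None = None,
) -> list[BurstEvent]:
    """Threshold search with hysteresis over the integrated trace.

    A burst is the maximal interval starting where the signal reaches the
    upper threshold and ending where it falls below the lower threshold
    (``hysteresis_frac * upper``). Bursts separated by gaps shorter than
    ``merge_gap`` are merged, then bursts shorter than ``min_Ti`` discarded.
    """
    if cfg.threshold_mode == "absolute":
        upper = float(cfg.threshold)
    else:
        upper = _robust_threshold(integrated, cfg, baseline_epoch)
    lower = cfg.hysteresis_frac * upper
    x = integrated.values
    n = x.size
    above = x >= upper
    below = x < lower

    spans: list[list[int]] = []  # [start, end) sample index pairs
    i = 0
    while i < n:
        rel = int(np.argmax(above[i:]))
        if not above[i + rel]:
            break
        start = i + rel
        rel = int(np.argmax(below[start:]))
        end = start + rel if below[start + rel] else n
        spans.append([start, end])
        i = end
    if not spans:
        return []

    gap_n = cfg.merge_gap * integrated.fs
    merged = [spans[0]]
    for start, end in spans[1:]:
        if start - merged[-1][1] < gap_n:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    min_n = cfg.min_Ti * integrated.fs
    events = []
    for start, end in merged:
        if end - start < min_n or end == start:
            continue
        events.append(
            BurstEvent(
                onset=integrated.t0 + start / integrated.fs,
                offset=integrated.t0 + end / integrated.fs,
                peak_amp=float(x[start:end].max()),
            )
        )
    return events


def respiratory_cycles(bursts: list[BurstEvent]) -> list[RespCycle]:
    """Build cycles from consecutive bursts; the last burst yields no cycle."""
    if len(bursts) < 2:
        logger.info("fewer than 2 bursts (%d): no respiratory cycles", len(bursts))
        return []
    cycles = []
    for b, nxt in zip(bursts[:-1], bursts[1:]):
        Ti = b.offset - b.onset
        Te = nxt.onset - b.offset
        if Te <= 0:
            raise ValidationError(
                f"bursts overlap or touch at t={b.offset:.4f}s (Te={Te})"
            )
        cycles.append(
            RespCycle(onset=b.onset, Ti=Ti, Te=Te, f_inst=1.0 / (Ti + Te),
                      peak_amp=b.peak_amp)
        )
    return cycles


def normalize_amplitude(
    cycles: list[RespCycle], baseline_cycles: list[RespCycle]
) -> np.ndarray:
    """Peak amplitudes as percent of the mean baseline peak amplitude."""
    if not baseline_cycles:
        raise ParameterError("amplitude normalization requires baseline cycles")
    base = float(np.mean([c.peak_amp for c in baseline_cycles]))
    return np.array([100.0 * c.peak_amp / base for c in cycles])


@dataclass
class WindowConfig:
    window_s: float = 6.0
    n_windows: int = 3
    skip_s: float = 20.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.n_windows < 1 or self.skip_s < 0:
            raise ParameterError("invalid measurement-window configuration")


@dataclass
class WindowStats:
    start: float
    end: float
    n_cycles: int
    f_mean: float
    Ti_mean: float
    Te_mean: float
    amp_mean: float


@dataclass
class MeasurementSummary:
    """Per-window means and their average (the per-animal value)."""

    windows: list[WindowStats] = field(default_factory=list)
    f_mean: float = float("nan")
    Ti_mean: float = float("nan")
    Te_mean: float = float("nan")
    amp_mean: float = float("nan")
    truncated: bool = False  # True when the epoch was too short for the request


def _window_stats(cycles: list[RespCycle], start: float, end: float) -> WindowStats:
    sel = [c for c in cycles if start <= c.onset < end]
    if not sel:
        return WindowStats(start, end, 0, np.nan, np.nan, np.nan, np.nan)
    return WindowStats(
        start=start,
        end=end,
        n_cycles=len(sel),
        f_mean=float(np.mean([c.f_inst for c in sel])),
        Ti_mean=float(np.mean([c.Ti for c in sel])),
        Te_mean=float(np.mean([c.Te for c in sel])),
        amp_mean=float(np.mean([c.peak_amp for c in sel])),
    )


def select_measurement_windows(
    cycles: list[RespCycle],
    run_epoch: tuple[float, float],
    cfg: WindowConfig | None = None,
) -> MeasurementSummary:
    """Average respiratory parameters over evenly spaced measurement windows.

    Windows are drawn from ``[run_start + skip_s, run_end]``, deterministic,
    non-overlapping and evenly spaced. If the epoch is too short for even one
    full window after the skip, the maximal single window is used and the
    result flagged ``truncated``.
    """
    cfg = cfg or WindowConfig()
    start, end = run_epoch
    if end <= start:
        raise ParameterError(f"empty run epoch ({start}, {end})")
    lo = start + cfg.skip_s
    span = end - lo
    if span < cfg.window_s:
        lo_eff = lo if span > 0 else start
        logger.warning(
            "run epoch (%.1f s) shorter than skip + window: using single "
            "window [%.1f, %.1f] s", end - start, lo_eff, end,
        )
        ws = _window_stats(cycles, lo_eff, end)
        return MeasurementSummary(
            windows=[ws], f_mean=ws.f_mean, Ti_mean=ws.Ti_mean,
            Te_mean=ws.Te_mean, amp_mean=ws.amp_mean, truncated=True,
        )
    n_eff = min(cfg.n_windows, int(span // cfg.window_s))
    if n_eff == 1:
        starts = [lo]
    else:
        starts = list(np.linspace(lo, end - cfg.window_s, n_eff))
    windows = [_window_stats(cycles, s, s + cfg.window_s) for s in starts]
    filled = [w for w in windows if w.n_cycles > 0]
    if not filled:
        return MeasurementSummary(windows=windows, truncated=False)
    return MeasurementSummary(
        windows=windows,
        f_mean=float(np.mean([w.f_mean for w in filled])),
        Ti_mean=float(np.mean([w.Ti_mean for w in filled])),
        Te_mean=float(np.mean([w.Te_mean for w in filled])),
        amp_mean=float(np.mean([w.amp_mean for w in filled])),
        truncated=False,
    )
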