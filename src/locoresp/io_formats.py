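"""Readers and writers for external representations.

Covers plain numeric time-series files, pose-estimation CSV exports
(three header rows: scorer / bodyparts / coords, then x, y, likelihood
columns per bodypart), YAML run configuration, and the flat result
tables written by the pipeline.

Unit conventions: all times are seconds, positions are centimetres after
calibration (``px / px_per_cm``, applied at read time). Sample ``i`` of a
time series covers the half-open interval ``[t0 + i/fs, t0 + (i+1)/fs)``.
"""

from __future__ import annotations

import dataclasses
import importlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ParameterError, ValidationError

CANONICAL_BODYPARTS = ("rHL", "lHL", "rFL", "lFL", "head")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """Uniformly sampled scalar signal.

    Parameters
    ----------
    values : array-like of float
        Sample values; must be finite and non-empty.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if self.values.size < 1:
            raise ValidationError("time series must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValidationError(f"non-finite sample at index {bad}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs, half-open sample convention)."""
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def slice(self, t_start: float, t_end: float) -> "TimeSeries":
        """Samples whose time lies in [t_start, t_end)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n, int(np.ceil((t_end - self.t0) * self.fs - 1e-9)))
        if i1 <= i0:
            raise ParameterError(
                f"empty slice [{t_start}, {t_end}) of record "
                f"[{self.t0}, {self.t0 + self.duration})"
            )
        return TimeSeries(self.values[i0:i1], self.fs, self.t0 + i0 / self.fs)


@dataclass
class PoseTrack:
    """Per-bodypart pose-estimation track (one row per video frame)."""

    bodypart: str
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.likelihood = np.asarray(self.likelihood, dtype=float).ravel()
        if not (self.x.size == self.y.size == self.likelihood.size):
            raise ValidationError(
                f"track '{self.bodypart}': x, y, likelihood lengths differ "
                f"({self.x.size}, {self.y.size}, {self.likelihood.size})"
            )
        if not self.fps > 0:
            raise ParameterError(f"fps must be > 0, got {self.fps}")
        bad = np.flatnonzero((self.likelihood < 0) | (self.likelihood > 1))
        if bad.size:
            raise ValidationError(
                f"track '{self.bodypart}': likelihood outside [0, 1] "
                f"at frame {int(bad[0])} (value {self.likelihood[bad[0]]})"
            )

    @property
    def n_frames(self) -> int:
        return int(self.x.size)


@dataclass
class SessionConfig:
    """Run configuration: acquisition geometry plus flat analysis parameters."""

    belt_speed: float = 0.0          # cm/s; 0 means overground/corridor
    incline_pct: float = 0.0
    px_per_cm: float = 1.0
    condition: str = ""
    fps: float = 200.0
    fs_emg: float = 2000.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise ParameterError(f"px_per_cm must be > 0, got {self.px_per_cm}")
        if self.belt_speed < 0:
            raise ParameterError(f"belt_speed must be >= 0, got {self.belt_speed}")


def load_config(path: str | Path) -> SessionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: top level of config must be a mapping")
    known = {f.name for f in dataclasses.fields(SessionConfig)} - {"params"}
    kwargs = {k: raw[k] for k in known if k in raw}
    kwargs["params"] = dict(raw.get("params", {}))
    return SessionConfig(**kwargs)


def save_config(cfg: SessionConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

def _read_pose_frame(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".h5", ".hdf5"}:
        # hierarchical binary export of the same table; needs pytables
        return pd.read_hdf(path)
    with open(path) as fh:
        header = [fh.readline() for _ in range(3)]
    labels = [line.split(",")[0].strip().lower() for line in header]
    expected = ["scorer", "bodyparts", "coords"]
    for lineno, (got, want) in enumerate(zip(labels, expected), start=1):
        if got != want:
            raise FormatError(
                f"{path}: malformed pose header at line {lineno}: "
                f"expected leading cell '{want}', got '{got or '<empty>'}'"
            )
    coords = {c.strip().lower() for c in header[2].split(",")[1:]}
    if not {"x", "y", "likelihood"} <= coords:
        raise FormatError(
            f"{path}: malformed pose header at line 3: needs x, y, likelihood columns"
        )
    return pd.read_csv(path, header=[0, 1, 2], index_col=0)


def read_pose_table(
    path: str | Path,
    fps: float,
    px_per_cm: float = 1.0,
    bodyparts: Sequence[str] = CANONICAL_BODYPARTS,
) -> dict[str, PoseTrack]:
    """Read a pose-estimation table into one :class:`PoseTrack` per bodypart.

    Bodypart matching is case-insensitive on the requested labels; positions
    are calibrated from pixels to centimetres by dividing by ``px_per_cm``.
    """
    path = Path(path)
    if not px_per_cm > 0:
        raise ParameterError(f"px_per_cm must be > 0, got {px_per_cm}")
    df = _read_pose_frame(path)
    available = {}  # lower-case bodypart -> actual column label
    for col in df.columns:
        available.setdefault(str(col[-2]).lower(), col[-2])
    tracks: dict[str, PoseTrack] = {}
    for bp in bodyparts:
        actual = available.get(bp.lower())
        if actual is None:
            raise ConfigurationError(
                f"{path}: required bodypart '{bp}' not found "
                f"(available: {sorted(available.values())})"
            )
        coord_cols = {
            str(col[-1]).lower(): col
            for col in df.columns if str(col[-2]) == actual
        }
        missing = {"x", "y", "likelihood"} - coord_cols.keys()
        if missing:
            raise FormatError(
                f"{path}: bodypart '{bp}' lacks columns {sorted(missing)}"
            )
        tracks[bp] = PoseTrack(
            bodypart=bp,
            x=df[coord_cols["x"]].to_numpy(dtype=float) / px_per_cm,
            y=df[coord_cols["y"]].to_numpy(dtype=float) / px_per_cm,
            likelihood=df[coord_cols["likelihood"]].to_numpy(dtype=float),
            fps=fps,
        )
    lengths = {t.n_frames for t in tracks.values()}
    if len(lengths) != 1:
        raise ValidationError(f"{path}: bodyparts have unequal frame counts {lengths}")
    return tracks


def write_pose_table(
    tracks: Mapping[str, PoseTrack],
    path: str | Path,
    scorer: str = "locoresp",
    px_per_cm: float = 1.0,
) -> None:
    """Write tracks in the 3-header-row CSV dialect (positions re-scaled to px)."""
    cols = {}
    for bp, tr in tracks.items():
        cols[(scorer, bp, "x")] = tr.x * px_per_cm
        cols[(scorer, bp, "y")] = tr.y * px_per_cm
        cols[(scorer, bp, "likelihood")] = tr.likelihood
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["scorer", "bodyparts", "coords"]
    )
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# numeric time-series files
# ---------------------------------------------------------------------------

def _load_columns(path: Path) -> np.ndarray:
    try:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        try:
            return np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: could not parse numeric data: {exc}") from exc


def read_timeseries(path: str | Path, fs: float | None = None) -> TimeSeries:
    """Read a one-column (value) or two-column (time, value) numeric text file.

    For one-column input ``fs`` is required. Two-column input must have
    uniform time spacing within 1e-6 relative tolerance; ``fs`` is then
    inferred from the time column when not given.
    """
    path = Path(path)
    data = _load_columns(path)
    if data.shape[1] == 1:
        if fs is None:
            raise ParameterError(f"{path}: single-column file requires an explicit fs")
        values, t0 = data[:, 0], 0.0
    elif data.shape[1] == 2:
        t, values = data[:, 0], data[:, 1]
        if t.size < 2:
            raise FormatError(f"{path}: two-column file needs at least 2 rows")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt.mean()) > 1e-6 * abs(dt.mean())):
            raise FormatError(f"{path}: time column is not uniformly spaced")
        if fs is None:
            fs = 1.0 / dt.mean()
        t0 = float(t[0])
    else:
        raise FormatError(f"{path}: expected 1 or 2 columns, got {data.shape[1]}")
    if np.any(~np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValidationError(f"{path}: non-finite value at row {bad}")
    return TimeSeries(values, fs=float(fs), t0=t0)


def write_timeseries(ts: TimeSeries, path: str | Path, two_column: bool = False) -> None:
    if two_column:
        np.savetxt(path, np.column_stack([ts.times(), ts.values]), fmt="%.17g")
    else:
        np.savetxt(path, ts.values, fmt="%.17g")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

# kind -> (defining module, class name, fixed column order)
_TABLE_SPECS: dict[str, tuple[str, str, list[str]]] = {
    "bursts": ("locoresp.emg_processing", "BurstEvent",
               ["onset", "offset", "peak_amp"]),
    "resp_cycles": ("locoresp.emg_processing", "RespCycle",
                    ["onset", "Ti", "Te", "f_inst", "peak_amp"]),
    "stride_cycles": ("locoresp.gait_kinematics", "StrideCycle",
                      ["limb", "footfall_prev", "liftoff", "footfall_next"]),
    "epochs": ("locoresp.gait_kinematics", "Epoch",
               ["start", "end", "label"]),
    "phases": ("locoresp.coupling_stats", "PhaseSample",
               ["phi", "insp_onset", "cycle_index", "ref_limb"]),
    "circular_stats": ("locoresp.coupling_stats", "CircularStats",
                       ["mean_phase", "R", "n"]),
}

_INT_COLUMNS = {"cycle_index", "n"}


def table_filename(kind: str) -> str:
    return f"{kind}.csv"


def write_result_tables(
    results: Mapping[str, Sequence], outdir: str | Path
) -> dict[str, Path]:
    """Write one CSV per result kind with a fixed, documented column order.

    Re-reading with :func:`read_result_table` reproduces the records exactly.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    paths: dict[str, Path] = {}
    for kind, records in results.items():
        if kind not in _TABLE_SPECS:
            raise ParameterError(f"unknown result table kind '{kind}'")
        _, _, columns = _TABLE_SPECS[kind]
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=columns)
        path = outdir / table_filename(kind)
        df.to_csv(path, index=False, float_format="%.17g")
        paths[kind] = path
    return paths


def read_result_table(kind: str, path: str | Path) -> list:
    if kind not in _TABLE_SPECS:
        raise ParameterError(f"unknown result table kind '{kind}'")
    module_name, cls_name, columns = _TABLE_SPECS[kind]
    cls = getattr(importlib.import_module(module_name), cls_name)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected columns {columns}, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        kwargs = dict(zip(columns, row))
        for key in _INT_COLUMNS & kwargs.keys():
            kwargs[key] = int(kwargs[key])
        records.append(cls(**kwargs))
    return records
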