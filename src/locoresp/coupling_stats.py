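"""Breath-within-stride statistics.

Assigns each inspiration onset a phase in [0, 1) within its enclosing
stride cycle (0 at the preceding footfall, 1 at the next), computes the
circular mean and concentration R of those phases, applies the fixed
R-threshold orientation criterion, builds phase histograms, computes
surrogate-calibrated cross-correlograms, and compares samples with the
Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, ValidationError
from .gait_kinematics import StrideCycle
from .io_formats import TimeSeries

#: minimum number of bursts for a verdict to be considered valid, per context
MIN_N = {"treadmill": 35, "airpuff": 20}

R_THRESHOLD_DEFAULT = 0.3


@dataclass
class PhaseSample:
    """Phase of one inspiration onset within a stride cycle."""

    phi: float
    insp_onset: float
    cycle_index: int
    ref_limb: str

    def __post_init__(self) -> None:
        if not (0 <= self.phi < 1):
            raise ValidationError(f"phi must be in [0, 1), got {self.phi}")


@dataclass
class PhaseAssignment:
    samples: list[PhaseSample] = field(default_factory=list)
    n_excluded: int = 0

    def phis(self) -> np.ndarray:
        return np.array([s.phi for s in self.samples])


@dataclass
class CircularStats:
    """Mean phase and concentration of a set of circular phases.

    ``mean_phase`` is NaN (undefined) when R is numerically zero.
    """

    mean_phase: float
    R: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.R <= 1 + 1e-12):
            raise ValidationError(f"R must be in [0, 1], got {self.R}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")


@dataclass
class OrientationVerdict:
    oriented: bool
    valid: bool
    R: float
    n: int
    context: str


@dataclass
class Correlogram:
    lags: np.ndarray
    r: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    flat: bool


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    exact: bool


# ---------------------------------------------------------------------------
# phase assignment and circular statistics
# ---------------------------------------------------------------------------

def inspiration_phases(
    insp_onsets, strides: list[StrideCycle]
) -> PhaseAssignment:
    """Assign each inspiration onset its phase within the enclosing stride.

    An onset ``t`` inside cycle ``[FF_prev, FF_next)`` gets
    ``phi = (t - FF_prev) / (FF_next - FF_prev)``; the convention is
    half-open, so an onset exactly at a footfall belongs to the cycle that
    starts there. Onsets outside every cycle are excluded and counted.
    """
    if not strides:
        raise ParameterError("inspiration_phases requires at least one stride cycle")
    prev = np.array([s.footfall_prev for s in strides])
    nxt = np.array([s.footfall_next for s in strides])
    if np.any(np.diff(prev) <= 0) or np.any(nxt[:-1] > prev[1:] + 1e-12):
        raise ValidationError("stride cycles must be ordered and non-overlapping")
    onsets = np.asarray(insp_onsets, dtype=float)
    ref_limb = strides[0].limb
    samples = []
    excluded = 0
    idx = np.searchsorted(prev, onsets, side="right") - 1
    for t, i in zip(onsets, idx):
        if i < 0 or t >= nxt[i]:
            excluded += 1
            continue
        phi = (t - prev[i]) / (nxt[i] - prev[i])
        samples.append(
            PhaseSample(phi=float(phi), insp_onset=float(t),
                        cycle_index=int(i), ref_limb=ref_limb)
        )
    return PhaseAssignment(samples=samples, n_excluded=excluded)


def circular_stats(phases) -> CircularStats:
    """Mean phase and mean resultant length R of phases on the unit circle."""
    phis = np.asarray(phases, dtype=float)
    if phis.size < 1:
        raise ParameterError("circular_stats requires at least one phase")
    theta = 2 * np.pi * phis
    c = float(np.cos(theta).mean())
    s = float(np.sin(theta).mean())
    r = min(math.hypot(c, s), 1.0)
    if r < 1e-12:
        mean = float("nan")
    else:
        mean = math.atan2(s, c) / (2 * np.pi) % 1.0
    return CircularStats(mean_phase=mean, R=r, n=int(phis.size))


def orientation_verdict(
    stats: CircularStats,
    context: str = "treadmill",
    R_threshold: float = R_THRESHOLD_DEFAULT,
    min_n: int | None = None,
) -> OrientationVerdict:
    """Fixed-threshold orientation criterion.

    ``oriented`` is True when R reaches the threshold; ``valid`` is True when
    enough bursts contributed (35 on the treadmill, 20 for air puff). Validity
    is a flag, never an exception.
    """
    if min_n is None:
        if context not in MIN_N:
            raise ParameterError(
                f"unknown context '{context}' (known: {sorted(MIN_N)}); "
                "pass min_n explicitly"
            )
        min_n = MIN_N[context]
    return OrientationVerdict(
        oriented=stats.R >= R_threshold,
        valid=stats.n >= min_n,
        R=stats.R,
        n=stats.n,
        context=context,
    )


def rayleigh_p(stats: CircularStats) -> float:
    """First-order Rayleigh approximation p = exp(-n R^2), clipped to (0, 1]."""
    p = math.exp(-stats.n * stats.R**2)
    return min(max(p, np.finfo(float).tiny), 1.0)


def phase_histogram(phases, n_bins: int = 10) -> np.ndarray:
    """Counts over equal-width half-open bins [k/n_bins, (k+1)/n_bins)."""
    phis = np.asarray(phases, dtype=float)
    if phis.size < 1:
        raise ParameterError("phase_histogram requires at least one phase")
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if np.any((phis < 0) | (phis >= 1)):
        raise ValidationError("phases must lie in [0, 1)")
    # exact half-open binning: floor(phi * n_bins), immune to edge rounding
    idx = np.minimum((phis * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


# ---------------------------------------------------------------------------
# cross-correlogram with circular-shift surrogates
# ---------------------------------------------------------------------------

def cross_correlogram(
    a: TimeSeries,
    b: TimeSeries,
    max_lag: float,
    n_surrogates: int = 1000,
    alpha: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> Correlogram:
    """Cross-correlogram of two equal-rate signals with a surrogate envelope.

    Both signals are z-scored and correlated at integer-sample lags in
    ``[-max_lag, max_lag]`` (circular convention). The null envelope comes
    from circular time-shifts of ``b`` (uniform shift of at least ``max_lag``,
    seeded): the ``1 - alpha`` quantile of the maximum absolute surrogate
    correlation over all lags gives a symmetric whole-curve band, so a null
    pair is declared flat with probability about ``1 - alpha``. ``flat`` is
    True iff r stays strictly inside the band at every lag.
    """
    if a.fs != b.fs:
        raise ParameterError(f"sampling rates differ ({a.fs} vs {b.fs})")
    n = min(a.n, b.n)
    lag_n = int(round(max_lag * a.fs))
    if lag_n < 1:
        raise ParameterError("max_lag must span at least one sample")
    if n < 4 * lag_n:
        raise ParameterError(
            f"overlapping support ({n} samples) must be >= 4 * max_lag ({4 * lag_n})"
        )
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    za, zb = [], []
    for name, ts in (("a", a), ("b", b)):
        v = ts.values[:n]
        sd = v.std()
        if sd == 0:
            raise ValidationError(f"signal {name} has zero variance")
        zs = (v - v.mean()) / sd
        (za if name == "a" else zb).append(zs)
    za, zb = za[0], zb[0]

    # circular cross-correlation c[k] = sum_i za[i] * zb[(i+k) mod n] / n
    fa = np.fft.rfft(za)
    fb = np.fft.rfft(zb)
    c = np.fft.irfft(np.conj(fa) * fb, n=n) / n

    lags_idx = np.arange(-lag_n, lag_n + 1)
    r = c[lags_idx % n]

    shifts = rng.integers(lag_n, n - lag_n + 1, size=n_surrogates)
    sur = c[(lags_idx[None, :] + shifts[:, None]) % n]
    q = float(np.quantile(np.abs(sur).max(axis=1), 1 - alpha))
    band_hi = np.full(lags_idx.size, q)
    band_lo = -band_hi
    # strictly inside: a correlation that exactly attains the surrogate
    # extreme (e.g. a periodic signal against itself) is not flat
    flat = bool(np.all(np.abs(r) < q))
    return Correlogram(
        lags=lags_idx / a.fs, r=r, band_lo=band_lo, band_hi=band_hi, flat=flat
    )


# ---------------------------------------------------------------------------
# rank and ratio statistics
# ---------------------------------------------------------------------------

_EXACT_MAX_MIN_N = 8
_EXACT_MAX_COMBINATIONS = 500_000


def mann_whitney_u(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test (U reported for sample ``a``).

    Exact p by full enumeration of labelings when the smaller sample has at
    most 8 values and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ParameterError("mann_whitney_u requires two non-empty samples")
    na, nb = xa.size, xb.size
    pooled = np.concatenate([xa, xb])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    nm = na * nb
    has_ties = np.unique(pooled).size < pooled.size

    if (
        not has_ties
        and min(na, nb) <= _EXACT_MAX_MIN_N
        and math.comb(na + nb, min(na, nb)) <= _EXACT_MAX_COMBINATIONS
    ):
        k = min(na, nb)
        u_obs = u_a if na <= nb else nm - u_a
        # U for the smaller sample from its rank positions (no ties)
        dist = np.array([
            sum(pos) - k * (k + 1) / 2
            for pos in combinations(range(1, na + nb + 1), k)
        ])
        u_lo = min(u_obs, nm - u_obs)
        u_hi = nm - u_lo
        count = np.count_nonzero(dist <= u_lo) + np.count_nonzero(dist >= u_hi)
        p = min(count / dist.size, 1.0)
        return MannWhitneyResult(U=u_a, p=p, exact=True)

    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nm / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(U=u_a, p=1.0, exact=False)
    mu = nm / 2.0
    diff = u_a - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2) if diff != 0 else 0.0
    p = min(2.0 * sps.norm.sf(abs(z)), 1.0)
    return MannWhitneyResult(U=u_a, p=p, exact=False)


def percent_of_baseline(run_mean: float, base_mean: float) -> float:
    """Ratio convention: 100 * run / baseline."""
    if base_mean <= 0:
        raise ParameterError(f"base_mean must be > 0, got {base_mean}")
    return 100.0 * run_mean / base_mean


def significance_mark(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
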