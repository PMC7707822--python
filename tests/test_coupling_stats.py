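import cmath
import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locoresp.coupling_stats import (
    CircularStats,
    circular_stats,
    cross_correlogram,
    inspiration_phases,
    mann_whitney_u,
    orientation_verdict,
    percent_of_baseline,
    phase_histogram,
    rayleigh_p,
    significance_mark,
)
from locoresp.errors import ParameterError, ValidationError
from locoresp.gait_kinematics import StrideCycle
from locoresp.io_formats import TimeSeries


def complex_sum_oracle(phases):
    """Independent oracle: R and mean from the complex sum |sum e^{i theta}|/n."""
    z = sum(cmath.exp(2j * math.pi * p) for p in phases) / len(phases)
    return abs(z), (cmath.phase(z) / (2 * math.pi)) % 1.0


def brute_force_mwu_p(a, b):
    """Exact two-sided p by enumerating every labeling of the pooled values."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_of(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y)

    u_obs = u_of(a, b)
    nm = na * len(b)
    u_lo, u_hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(sa, sb)
        total += 1
        if u <= u_lo or u >= u_hi:
            count += 1
    return count / total


def _strides(footfalls, limb="rHL"):
    out = []
    for a, b in zip(footfalls[:-1], footfalls[1:]):
        out.append(StrideCycle(limb, a, a + 0.6 * (b - a), b))
    return out


class TestInspirationPhases:
    def test_simple_quarter_phase(self):
        pa = inspiration_phases([0.125], _strides([0.0, 0.5]))
        assert len(pa.samples) == 1
        assert pa.samples[0].phi == pytest.approx(0.25)
        assert pa.n_excluded == 0

    def test_onset_at_footfall_belongs_to_starting_cycle(self):
        pa = inspiration_phases([0.4], _strides([0.0, 0.4, 0.8]))
        (s,) = pa.samples
        assert s.phi == pytest.approx(0.0)
        assert s.cycle_index == 1

    def test_out_of_range_onsets_excluded(self):
        pa = inspiration_phases([0.1, 0.5, 0.9], _strides([0.0, 0.4, 0.8]))
        phis = [s.phi for s in pa.samples]
        np.testing.assert_allclose(phis, [0.25, 0.25])
        assert pa.n_excluded == 1

    def test_empty_strides_rejected(self):
        with pytest.raises(ParameterError):
            inspiration_phases([0.1], [])

    def test_gap_between_cycles_excludes_onsets(self):
        strides = [StrideCycle("rHL", 0.0, 0.2, 0.4),
                   StrideCycle("rHL", 0.6, 0.8, 1.0)]
        pa = inspiration_phases([0.5], strides)
        assert pa.samples == []
        assert pa.n_excluded == 1


class TestCircularStats:
    def test_all_identical(self):
        stats = circular_stats([0.25] * 10)
        assert stats.R == pytest.approx(1.0)
        assert stats.mean_phase == pytest.approx(0.25)

    def test_symmetric_four_points(self):
        stats = circular_stats([0.0, 0.25, 0.5, 0.75])
        assert stats.R == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(stats.mean_phase)

    def test_against_complex_sum_oracle(self):
        phases = [0.1, 0.2, 0.3]
        stats = circular_stats(phases)
        r_oracle, mean_oracle = complex_sum_oracle(phases)
        assert stats.R == pytest.approx(r_oracle, abs=1e-12)
        assert stats.mean_phase == pytest.approx(mean_oracle, abs=1e-12)
        assert stats.R == pytest.approx(0.8727, abs=5e-4)
        assert stats.mean_phase == pytest.approx(0.2, abs=1e-9)

    def test_oracle_agreement_on_random_sets(self, rng):
        for _ in range(200):
            phases = rng.uniform(0, 1, rng.integers(1, 60))
            stats = circular_stats(phases)
            r_oracle, mean_oracle = complex_sum_oracle(phases)
            assert abs(stats.R - r_oracle) < 1e-12
            if stats.R > 1e-9:
                d = abs(stats.mean_phase - mean_oracle) % 1.0
                assert min(d, 1 - d) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(
        phases=st.lists(st.floats(min_value=0, max_value=0.999), min_size=2,
                        max_size=30),
        rot=st.floats(min_value=0, max_value=1),
    )
    def test_rotation_invariance(self, phases, rot):
        base = circular_stats(phases)
        rotated = circular_stats([(p + rot) % 1.0 for p in phases])
        assert rotated.R == pytest.approx(base.R, abs=1e-9)
        if base.R > 1e-6:
            d = abs(rotated.mean_phase - (base.mean_phase + rot) % 1.0) % 1.0
            assert min(d, 1 - d) < 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            circular_stats([])


class TestOrientationVerdict:
    def test_oriented_and_valid(self):
        v = orientation_verdict(CircularStats(0.3, 0.87, 40), "treadmill")
        assert v.oriented and v.valid

    def test_low_r_not_oriented(self):
        v = orientation_verdict(CircularStats(0.3, 0.10, 40), "treadmill")
        assert not v.oriented and v.valid

    def test_small_n_invalid_on_treadmill(self):
        v = orientation_verdict(CircularStats(0.3, 0.5, 10), "treadmill")
        assert v.oriented and not v.valid

    def test_airpuff_min_n_is_20(self):
        v = orientation_verdict(CircularStats(0.3, 0.5, 25), "airpuff")
        assert v.valid
        assert not orientation_verdict(CircularStats(0.3, 0.5, 19), "airpuff").valid


class TestRayleighP:
    def test_r_zero_gives_one(self):
        assert rayleigh_p(CircularStats(float("nan"), 0.0, 40)) == 1.0

    def test_formula_value(self):
        p = rayleigh_p(CircularStats(0.5, 0.3, 40))
        assert p == pytest.approx(math.exp(-3.6))

    def test_monotone_in_n(self):
        ps = [rayleigh_p(CircularStats(0.5, 0.3, n)) for n in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(ps[:-1], ps[1:]))


class TestPhaseHistogram:
    def test_uniform_grid(self):
        phases = np.arange(40) / 40.0
        counts = phase_histogram(phases, n_bins=10)
        np.testing.assert_array_equal(counts, np.full(10, 4))

    def test_single_bin(self):
        counts = phase_histogram([0.05] * 7, n_bins=10)
        assert counts[0] == 7
        assert counts[1:].sum() == 0

    def test_boundary_goes_to_last_bin(self):
        counts = phase_histogram([0.999], n_bins=10)
        assert counts[9] == 1

    @settings(max_examples=50, deadline=None)
    @given(phases=st.lists(st.floats(min_value=0, max_value=0.999), min_size=1,
                           max_size=100))
    def test_counts_sum_to_n_and_merge_preserves_totals(self, phases):
        counts = phase_histogram(phases, n_bins=10)
        assert counts.sum() == len(phases)
        merged = counts.reshape(5, 2).sum(axis=1)
        assert merged.sum() == len(phases)
        assert merged.size == 5


class TestCrossCorrelogram:
    def _sine(self, n=4000, fs=200.0, f=5.0, phase=0.0):
        t = np.arange(n) / fs
        return TimeSeries(np.sin(2 * np.pi * f * t + phase), fs=fs)

    def test_identical_signals(self):
        a = self._sine()
        cg = cross_correlogram(a, a, max_lag=1.0, rng=0)
        i0 = np.argmin(np.abs(cg.lags))
        assert cg.r[i0] == pytest.approx(1.0)
        assert not cg.flat

    def test_delayed_copy_peaks_at_lag(self, rng):
        fs = 200.0
        x = rng.standard_normal(6000)
        delay = 37  # samples
        a = TimeSeries(x[delay:], fs=fs)
        b = TimeSeries(x[:-delay], fs=fs)
        # b[i] = a[i - delay] (b lags a): peak expected at +delay samples
        cg = cross_correlogram(a, b, max_lag=0.5, rng=1)
        peak_lag = cg.lags[np.argmax(cg.r)]
        assert peak_lag == pytest.approx(delay / fs, abs=1.0 / fs)
        assert not cg.flat

    def test_independent_noise_mostly_flat(self):
        # record much longer than the lag window, else the whole-curve
        # surrogate band is not calibrated
        flat = 0
        n_rep = 10
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            a = TimeSeries(r.standard_normal(20_000), fs=200.0)
            b = TimeSeries(r.standard_normal(20_000), fs=200.0)
            cg = cross_correlogram(a, b, max_lag=0.5, n_surrogates=400,
                                   rng=seed + 1000)
            flat += cg.flat
        assert flat >= n_rep - 1

    def test_zero_variance_rejected(self):
        a = TimeSeries(np.ones(1000), fs=100.0)
        b = TimeSeries(np.random.default_rng(0).normal(size=1000), fs=100.0)
        with pytest.raises(ValidationError):
            cross_correlogram(a, b, max_lag=0.5, rng=0)

    def test_rate_mismatch_rejected(self):
        a = TimeSeries(np.zeros(100) + np.arange(100), fs=100.0)
        b = TimeSeries(np.arange(100), fs=200.0)
        with pytest.raises(ParameterError):
            cross_correlogram(a, b, max_lag=0.1, rng=0)


class TestMannWhitney:
    def test_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.exact
        assert res.p == pytest.approx(0.1)

    def test_identical_multisets(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0, abs=0.05)

    def test_swap_symmetry(self):
        a, b = [1.2, 3.4, 2.2, 5.1], [0.5, 2.9, 4.4]
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert r1.p == pytest.approx(r2.p)
        assert r2.U == pytest.approx(len(a) * len(b) - r1.U)

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(20):
            na, nb = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, na + nb + 1.0))
            a, b = list(pooled[:na]), list(pooled[na:])
            res = mann_whitney_u(a, b)
            assert res.exact
            assert res.p == pytest.approx(brute_force_mwu_p(a, b))

    def test_normal_branch_reasonable(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        res = mann_whitney_u(a, b)
        assert not res.exact
        assert res.p < 0.001

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_u([], [1.0])


class TestPercentOfBaseline:
    def test_identity(self):
        assert percent_of_baseline(4.0, 4.0) == pytest.approx(100.0)

    def test_ratio(self):
        assert percent_of_baseline(9.0, 4.0) == pytest.approx(225.0)

    def test_fractional(self):
        assert percent_of_baseline(8.0, 3.5) == pytest.approx(228.57, abs=0.01)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterError):
            percent_of_baseline(1.0, 0.0)


class TestSignificanceMark:
    @pytest.mark.parametrize("p,mark", [
        (0.2, "ns"), (0.05, "ns"), (0.02, "*"), (0.005, "**"), (0.0005, "***"),
    ])
    def test_bands(self, p, mark):
        assert significance_mark(p) == mark


def test_null_calibration_small():
    """Under uniform phases at n=40, P(R >= 0.3) is near exp(-3.6) ~ 0.027."""
    rng = np.random.default_rng(42)
    hits = sum(
        circular_stats(rng.uniform(0, 1, 40)).R >= 0.3 for _ in range(500)
    )
    assert hits / 500 <= 0.05
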