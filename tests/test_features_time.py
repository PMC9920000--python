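"""Time-domain feature block: statistics, gait metrics and LCSS similarity."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claudigait.features_time import (
    WindowSignals,
    basic_stats,
    cadence,
    extract_time_features,
    histogram10,
    kurtosis,
    lcss_length,
    lcss_similarity,
    mean_stride_time,
    rmsr,
    skewness,
    sma,
    swing_stance_ratio,
    time_feature_names,
)
from claudigait.gait_events import GaitCycle, GaitEvents

FS = 50.0


def _window(rng, n=500, n_cycles=8):
    """Random window with synthetic cycles covering consecutive 55-sample strides."""
    sig = rng.normal(1.0, 0.5, size=(n, 3))
    mag = np.linalg.norm(sig, axis=1)
    starts = np.arange(0, n_cycles + 1) * 55
    cycles = [
        GaitCycle(start=int(a), end=int(b), fs=FS, rto=int(a + 33))
        for a, b in zip(starts[:-1], starts[1:])
    ]
    events = GaitEvents(rhc=starts, lhc=starts[:-1] + 27, rto=starts[:-1] + 33,
                        lto=starts[:-1] + 11, fs=FS)
    return WindowSignals(magnitude=mag, ax=sig[:, 0], ay=sig[:, 1], az=sig[:, 2],
                         fs=FS, cycles=cycles, events=events)


class TestBasicStats:
    def test_hand_example(self):
        s = basic_stats(np.array([1, 2, 3, 4, 5], dtype=float))
        assert s["mean"] == 3 and s["median"] == 3
        assert s["std"] == pytest.approx(np.sqrt(2.5))
        assert s["max"] == 5 and s["min"] == 1

    def test_constant(self):
        s = basic_stats(np.full(10, 2.2))
        assert s["max"] == s["min"] == s["mean"] == s["median"] == 2.2
        assert s["std"] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_order_statistics(self, seed):
        x = np.random.default_rng(seed).normal(size=37)
        s = basic_stats(x)
        assert s["min"] <= s["median"] <= s["max"]


class TestHistogram10:
    def test_uniform_grid(self):
        freqs = histogram10(np.arange(100) / 100.0)
        np.testing.assert_allclose(freqs, 0.10)

    def test_constant_all_mass_in_first_bin(self):
        np.testing.assert_array_equal(histogram10(np.full(7, 3.0)),
                                      [1, 0, 0, 0, 0, 0, 0, 0, 0, 0])

    def test_frequencies_sum_to_one(self, rng):
        for _ in range(5):
            assert histogram10(rng.normal(size=200)).sum() == pytest.approx(1.0)


class TestRmsr:
    def test_identical_axes(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_allclose(rmsr(x, x, x), 1 / np.sqrt(3))

    def test_single_active_axis(self):
        z = np.zeros(50)
        y = np.ones(50)
        np.testing.assert_allclose(rmsr(z, y, z), [0, 1, 0])

    def test_squares_sum_to_one(self, rng):
        for _ in range(10):
            r = rmsr(*rng.normal(size=(3, 80)))
            assert np.sum(r**2) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_flagged(self):
        z = np.zeros(10)
        assert np.all(np.isnan(rmsr(z, z, z)))


class TestMoments:
    def test_sma_examples_and_oracle(self, rng):
        one = np.ones(10)
        assert sma(one, one, one) == pytest.approx(3.0)
        assert sma(one * 0, one * 0, one * 0) == 0.0
        a, b, c = rng.normal(size=(3, 64))
        brute = sum(abs(a[i]) + abs(b[i]) + abs(c[i]) for i in range(64)) / 64
        assert sma(a, b, c) == pytest.approx(brute, rel=1e-12)

    def test_kurtosis_normal_sample(self):
        x = np.random.default_rng(7).normal(size=100_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_kurtosis_two_point_mass(self):
        x = np.tile([-1.0, 1.0], 50)
        assert kurtosis(x) == pytest.approx(1.0)

    def test_kurtosis_brute_force(self, rng):
        x = rng.normal(size=200)
        d = x - x.mean()
        brute = len(x) * np.sum(d**4) / np.sum(d**2) ** 2
        assert kurtosis(x) == pytest.approx(brute, rel=1e-12)

    def test_kurtosis_zero_variance_flagged(self):
        assert np.isnan(kurtosis(np.full(10, 1.0)))

    def test_skewness_symmetric_is_zero(self):
        x = np.concatenate([np.arange(10), -np.arange(10)]).astype(float)
        assert skewness(x) == pytest.approx(0.0, abs=1e-9)

    def test_skewness_hand_example(self):
        # [0,0,0,1]: m2 = 0.1875, m3 = 0.09375, g = 0.09375/0.1875^1.5
        assert skewness(np.array([0.0, 0, 0, 1])) == pytest.approx(1.1547, abs=1e-4)

    def test_skewness_sign_flips_under_negation(self, rng):
        x = rng.exponential(size=100)
        assert skewness(-x) == pytest.approx(-skewness(x), rel=1e-9)


class TestLcss:
    def test_identical_cycles(self):
        c = np.sin(np.arange(40) / 5.0)
        assert lcss_similarity([c, c.copy()]) == pytest.approx(1.0)

    def test_disjoint_constants(self):
        a, b = np.zeros(20), np.full(20, 10.0)
        assert lcss_similarity([a, b], eps=0.5) == 0.0

    def test_fewer_than_two_cycles_flagged(self):
        assert np.isnan(lcss_similarity([np.ones(10)]))

    def test_matches_exponential_brute_force(self, rng):
        def brute(a, b, eps, delta):
            @lru_cache(None)
            def f(i, j):
                if i == 0 or j == 0:
                    return 0
                best = max(f(i - 1, j), f(i, j - 1))
                if abs(a[i - 1] - b[j - 1]) <= eps and abs(i - j) <= delta:
                    best = max(best, f(i - 1, j - 1) + 1)
                return best

            return f(len(a), len(b))

        for _ in range(60):
            n, m = rng.integers(1, 13, size=2)
            a = rng.integers(0, 4, size=n).astype(float)
            b = rng.integers(0, 4, size=m).astype(float)
            eps = float(rng.choice([0.0, 0.5, 1.0]))
            delta = int(rng.integers(1, 6))
            assert lcss_length(a, b, eps, delta) == brute(tuple(a), tuple(b), eps, delta)


class TestGaitMetrics:
    def test_cadence_arithmetic(self):
        ev = GaitEvents(rhc=np.arange(9) * 55, lhc=np.arange(9) * 55 + 27,
                        rto=[], lto=[], fs=FS)
        assert cadence(ev, duration=10.0) == pytest.approx(108.0)
        assert cadence(None, duration=10.0) == 0.0

    def test_cadence_simulator(self, walk60):
        dur = len(walk60.detection.y_detrended) / FS
        steps_per_min = cadence(walk60.detection.events, dur)
        true_rate = 2 * 60.0 / walk60.sim_config.stride_time_mean
        assert steps_per_min == pytest.approx(true_rate, abs=6.0)

    def test_mean_stride_time(self):
        cycles = [GaitCycle(0, 50, FS), GaitCycle(50, 110, FS)]
        assert mean_stride_time(cycles) == pytest.approx(1.1)
        assert mean_stride_time([GaitCycle(0, 61, FS)]) == pytest.approx(1.22)
        assert np.isnan(mean_stride_time([]))

    def test_swing_stance_examples(self):
        c = GaitCycle(start=0, end=50, fs=FS, rto=30)  # stance 0.6 of 1.0 s
        assert swing_stance_ratio([c]) == pytest.approx(60.0)
        degenerate = GaitCycle(start=0, end=50, fs=FS, rto=50)
        assert swing_stance_ratio([degenerate]) == pytest.approx(100.0)
        assert np.isnan(swing_stance_ratio([GaitCycle(0, 50, FS)]))

    def test_swing_minus_stance_mode(self):
        c = GaitCycle(start=0, end=50, fs=FS, rto=30)
        assert swing_stance_ratio([c], mode="swing_minus_stance") == pytest.approx(-20.0)


class TestBlock:
    def test_exactly_70_named_values(self, rng):
        feats = extract_time_features(_window(rng))
        assert list(feats.keys()) == time_feature_names()
        assert len(feats) == 70

    def test_scale_equivariance(self, rng):
        w = _window(rng)
        c = 3.7
        scaled = WindowSignals(magnitude=c * w.magnitude, ax=c * w.ax, ay=c * w.ay,
                               az=c * w.az, fs=FS, cycles=w.cycles, events=w.events)
        f0 = extract_time_features(w)
        f1 = extract_time_features(scaled)
        for name in f0:
            stat = name.split("_")[0]
            if stat in ("max", "min", "mean", "median", "std") or name == "sma":
                assert f1[name] == pytest.approx(c * f0[name], rel=1e-9)
            else:  # histogram, rmsr, moments, similarity, gait metrics
                assert f1[name] == pytest.approx(f0[name], rel=1e-6, abs=1e-9)
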