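"""SSA decomposition and heel-contact / toe-off detection."""

import numpy as np
import pytest

from claudigait.gait_events import (
    GaitEvents,
    assign_left_right,
    detect_gait_events,
    detect_heel_contacts,
    detect_toe_offs,
    dominant_minima,
    dominant_oscillation,
    remove_trend,
    segment_cycles,
    ssa_decompose,
)

FS = 50.0


class TestSsaDecompose:
    def test_sinusoid_occupies_leading_pair(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 1.8 * t)
        d = ssa_decompose(x, L=100, fs=FS)
        energy = d.eigenvalues / d.eigenvalues.sum()
        assert energy[:2].sum() >= 0.99

    def test_constant_input_single_component(self):
        d = ssa_decompose(np.full(200, 2.5), L=50, fs=FS)
        np.testing.assert_allclose(d.components[0], 2.5, atol=1e-9)
        assert d.eigenvalues[1] <= 1e-12 * d.eigenvalues[0]

    def test_reconstruction_identity(self, rng):
        x = rng.normal(size=300)
        d = ssa_decompose(x, L=60, fs=FS)
        rel = np.abs(d.components.sum(axis=0) - x).max() / np.abs(x).max()
        assert rel <= 1e-6

    def test_eigenvalues_sorted_descending(self, rng):
        d = ssa_decompose(rng.normal(size=250), L=40, fs=FS)
        assert np.all(np.diff(d.eigenvalues) <= 1e-12)

    @pytest.mark.parametrize("L", [1, 300])
    def test_embedding_length_bounds(self, L):
        with pytest.raises(ValueError, match="embedding length"):
            ssa_decompose(np.zeros(400), L=L)


class TestRemoveTrend:
    def test_ramp_plus_sinusoid(self):
        t = np.arange(500) / FS
        sine = np.sin(2 * np.pi * 2.0 * t)
        x = 3.0 * t + sine
        detrended, trend = remove_trend(ssa_decompose(x, L=100, fs=FS))
        assert np.corrcoef(detrended, sine)[0, 1] >= 0.99
        assert np.corrcoef(trend, 3.0 * t)[0, 1] >= 0.99

    def test_pure_oscillation_has_no_trend(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 1.8 * t)
        _, trend = remove_trend(ssa_decompose(x, L=100, fs=FS))
        assert np.sqrt(np.mean(trend**2)) <= 0.01 * np.sqrt(np.mean(x**2))

    def test_detrending_leaves_event_timing(self):
        """Slow drift shifts no extrema of the oscillatory part."""
        t = np.arange(500) / FS
        sine = np.cos(2 * np.pi * 1.8 * t)
        drift = 2.0 * np.sin(2 * np.pi * 0.05 * t)
        detrended, _ = remove_trend(ssa_decompose(sine + drift, L=100, fs=FS))
        clean_minima = dominant_minima(dominant_oscillation(sine, 100, FS), FS)
        drift_minima = dominant_minima(dominant_oscillation(detrended, 100, FS), FS)
        matched = [np.min(np.abs(drift_minima - m)) for m in clean_minima[1:-1]]
        assert np.max(matched) <= 1


class TestDominantOscillation:
    def test_pure_sinusoid_reproduced(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 1.8 * t + 0.7)
        y = dominant_oscillation(x, L=100, fs=FS)
        assert np.corrcoef(x, y)[0, 1] >= 0.999

    def test_noisy_sinusoid_recovered(self, rng):
        t = np.arange(500) / FS
        clean = np.sin(2 * np.pi * 1.8 * t)
        noisy = clean + rng.normal(0, 10 ** (-5 / 20), size=len(t))  # 5 dB SNR
        y = dominant_oscillation(noisy, L=100, fs=FS)
        assert np.corrcoef(clean, y)[0, 1] >= 0.95

    def test_extrema_spacing_matches_step_period(self, walk60):
        y_dom = walk60.detection.y_dominant
        minima = dominant_minima(y_dom, FS)
        spacing = np.median(np.diff(minima)) / FS
        step = walk60.sim_config.stride_time_mean / 2
        assert spacing == pytest.approx(step, rel=0.10)


class TestDetectHeelContacts:
    def test_simulator_contacts_recovered(self, walk60):
        det = walk60.detected_contact_times()
        true = walk60.true_contact_times()
        errs = np.array([np.min(np.abs(det - t)) for t in true])
        assert np.median(errs) <= 0.1
        assert np.mean(errs <= 0.1) >= 0.90

    def test_constructed_spike_hit_exactly(self):
        t = np.arange(500) / FS
        y_dom = -np.cos(2 * np.pi * 2.0 * t)  # minima every 25 samples
        y_rec = np.ones(500)
        spikes = np.flatnonzero(np.isclose(y_dom, -1.0, atol=1e-9)) + 3
        spikes = spikes[spikes < 500]
        y_rec[spikes] = -10.0
        contacts = detect_heel_contacts(y_dom, y_rec, np.ones(500), FS)
        assert set(contacts) <= set(spikes)
        assert len(contacts) >= len(spikes) - 2

    def test_constant_signal_no_events(self):
        x = np.zeros(500)
        assert len(detect_heel_contacts(x, x, x, FS)) == 0


class TestAssignLeftRight:
    def _setup(self, mean_first, mean_second):
        y = np.zeros(150)
        y[0:50] = mean_first
        y[50:100] = mean_second
        minima = np.array([0, 50, 100])
        contacts = np.array([2, 52, 102])
        return contacts, y, minima

    def test_larger_first_segment_mean_is_right(self):
        contacts, y, minima = self._setup(2.0, 1.0)
        rhc, lhc = assign_left_right(contacts, y, minima)
        assert list(rhc) == [2, 102] and list(lhc) == [52]

    def test_larger_second_segment_mean_is_left(self):
        contacts, y, minima = self._setup(1.0, 2.0)
        rhc, lhc = assign_left_right(contacts, y, minima)
        assert list(rhc) == [52] and list(lhc) == [2, 102]

    def test_tie_defaults_right_with_warning(self):
        contacts, y, minima = self._setup(1.0, 1.0)
        with pytest.warns(UserWarning, match="parity tie"):
            rhc, _ = assign_left_right(contacts, y, minima)
        assert rhc[0] == 2

    def test_simulator_pocket_side_agreement(self, walk60):
        """Detected 'right' contacts fall on the simulated pocket side >=90%."""
        ev = walk60.detection.events
        truth = walk60.truth
        det_r = ev.rhc / FS + walk60.analysis_start_s
        hits = 0
        for t in det_r:
            j = np.argmin(np.abs(truth.heel_contact_times - t))
            hits += truth.heel_contact_sides[j] == "R"
        assert hits / len(det_r) >= 0.90


class TestDetectToeOffs:
    def test_unique_candidate_found(self):
        y = np.zeros(100)
        y[60] = -5.0  # single local minimum between LHC=50 and next RHC=80
        y[30] = 5.0   # single local maximum between RHC=0 and LHC=50
        rto, lto = detect_toe_offs(np.array([0, 80]), np.array([50]), y, FS)
        assert list(rto) == [60]
        assert list(lto) == [30]

    def test_two_contacts_no_crash(self):
        rto, lto = detect_toe_offs(np.array([0]), np.array([25]), np.zeros(100), FS)
        assert len(rto) == 0 and len(lto) == 0

    def test_simulator_stance_fraction(self, walk60):
        fractions = [
            c.stance_time / c.stride_time
            for c in walk60.detection.cycles
            if c.stance_time is not None
        ]
        assert len(fractions) > 10
        true_c = walk60.sim_config.stance_fraction
        assert np.mean(fractions) == pytest.approx(true_c, abs=0.10)


class TestSegmentCycles:
    def test_stride_arithmetic(self):
        ev = GaitEvents(rhc=[0, 50, 100], lhc=[25, 75], rto=[30, 80], lto=[5, 55], fs=FS)
        cycles = segment_cycles(ev)
        assert len(cycles) == 2
        assert cycles[0].stride_time == pytest.approx(1.0)
        assert cycles[0].stance_time == pytest.approx(0.6)
        assert cycles[0].swing_time == pytest.approx(0.4)

    def test_empty_events(self):
        assert segment_cycles(GaitEvents(rhc=[], lhc=[], rto=[], lto=[], fs=FS)) == []

    def test_stride_and_stance_plus_swing_consistent(self, walk60):
        for c in walk60.detection.cycles:
            if c.stance_time is not None:
                assert c.stance_time + c.swing_time == pytest.approx(
                    c.stride_time, abs=1.0 / FS
                )

    def test_simulator_stride_time(self, walk60):
        strides = [c.stride_time for c in walk60.detection.cycles]
        assert np.mean(strides) == pytest.approx(
            walk60.sim_config.stride_time_mean, abs=0.05
        )


class TestInvariants:
    def test_event_ordering_in_complete_cycles(self, walk60):
        for c in walk60.detection.cycles:
            if None in (c.lto, c.lhc, c.rto):
                continue
            assert c.start < c.lto < c.lhc < c.rto < c.end

    def test_amplitude_scale_invariance(self, walk60):
        accel = walk60.walk.earth.accel_earth[250:]
        base = detect_gait_events(accel[:, 1], accel[:, 2], FS)
        scaled = detect_gait_events(7.3 * accel[:, 1], 7.3 * accel[:, 2], FS)
        np.testing.assert_array_equal(base.events.rhc, scaled.events.rhc)
        np.testing.assert_array_equal(base.events.lhc, scaled.events.lhc)
        np.testing.assert_array_equal(base.events.rto, scaled.events.rto)
        np.testing.assert_array_equal(base.events.lto, scaled.events.lto)
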