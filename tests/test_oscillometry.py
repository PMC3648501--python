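"""Oscillation metrics on closed-form signals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somiteclock import (
    Trajectory,
    count_periods,
    detect_peaks,
    measure,
    phase_relation,
    response_delay,
)


def make_sine(period=120.0, t_end=600.0, dt=1.0, amplitude=1.0, baseline=2.0,
              phase=0.0, name="s"):
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = baseline + amplitude * np.sin(2 * np.pi * (t - phase) / period)
    return Trajectory(t, y[None, :], [name])


class TestDetectPeaks:
    def test_sine_peak_times(self):
        traj = make_sine(period=120.0, t_end=600.0)
        peaks = detect_peaks(traj, "s")
        assert np.allclose(peaks, [30, 150, 270, 390, 510], atol=1.5)

    def test_constant_signal_has_no_peaks(self):
        t = np.arange(0, 100.0, 1.0)
        traj = Trajectory(t, np.full((1, len(t)), 3.0), ["s"])
        assert len(detect_peaks(traj, "s")) == 0

    def test_small_ripples_filtered_by_prominence(self):
        traj = make_sine(period=120.0, t_end=600.0)
        ripple = 0.02 * np.sin(2 * np.pi * traj.times / 7.0)
        noisy = Trajectory(traj.times, (traj["s"] + ripple)[None, :], ["s"])
        assert len(detect_peaks(noisy, "s")) == 5


class TestMeasure:
    def test_sine_summary(self):
        traj = make_sine(period=120.0, t_end=600.0, amplitude=1.0,
                               baseline=2.0)
        s = measure(traj, "s")
        assert s.is_oscillating
        assert s.period == pytest.approx(120.0, abs=1.0)
        assert s.amplitude == pytest.approx(2.0, abs=0.05)

    def test_decaying_exponential_not_oscillating(self):
        t = np.arange(0, 600.0, 1.0)
        traj = Trajectory(t, np.exp(-t / 100.0)[None, :], ["s"])
        assert not measure(traj, "s").is_oscillating

    def test_shallow_modulation_below_floor(self):
        traj = make_sine(amplitude=0.02, baseline=2.0)
        s = measure(traj, "s")
        assert s.relative_amplitude < 0.05
        assert not s.is_oscillating

    @given(period=st.floats(min_value=30.0, max_value=240.0))
    @settings(max_examples=25, deadline=None)
    def test_period_recovered_within_sample_interval(self, period):
        traj = make_sine(period=period, t_end=8 * period, dt=1.0)
        s = measure(traj, "s")
        assert s.is_oscillating
        assert abs(s.period - period) <= 1.0


class TestPhaseRelation:
    def test_identical_signals_in_phase(self):
        a = make_sine(name="a")
        b = make_sine(name="b")
        traj = Trajectory(a.times, np.vstack([a.values, b.values]), ["a", "b"])
        pr = phase_relation(traj, "a", "b")
        assert pr.classification.value == "in_phase"
        assert abs(pr.lag) < 2.0

    def test_half_period_shift_is_antiphase(self):
        a = make_sine(name="a")
        b = make_sine(name="b", phase=60.0)
        traj = Trajectory(a.times, np.vstack([a.values, b.values]), ["a", "b"])
        assert phase_relation(traj, "a", "b").classification.value == "antiphase"

    def test_lag_antisymmetry(self):
        a = make_sine(name="a")
        b = make_sine(name="b", phase=25.0)
        traj = Trajectory(a.times, np.vstack([a.values, b.values]), ["a", "b"])
        assert phase_relation(traj, "a", "b").lag == pytest.approx(
            -phase_relation(traj, "b", "a").lag, abs=1.0)

    def test_non_oscillating_species_raises(self):
        a = make_sine(name="a")
        flat = np.full_like(a.values, 2.0)
        traj = Trajectory(a.times, np.vstack([a.values, flat]), ["a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            phase_relation(traj, "a", "b")


class TestCountPeriods:
    def test_sine_on_1200_min(self):
        traj = make_sine(period=120.0, t_end=1200.0)
        assert count_periods(traj, "s") == 9  # 10 peaks -> 9 full cycles

    def test_constant_counts_zero(self):
        t = np.arange(0, 1200.0, 1.0)
        traj = Trajectory(t, np.ones((1, len(t))), ["s"])
        assert count_periods(traj, "s") == 0

    def test_invariant_under_amplitude_scaling(self):
        traj = make_sine(period=120.0, t_end=1200.0)
        scaled = Trajectory(traj.times, traj.values * 37.0, ["s"])
        assert count_periods(traj, "s") == count_periods(scaled, "s")


class TestResponseDelay:
    def test_identical_trajectories_no_response(self):
        traj = make_sine(t_end=1200.0)
        assert np.isnan(response_delay(traj, traj, "s", 120.0))

    def test_step_change_detected_quickly(self):
        ref = make_sine(t_end=1200.0, baseline=2.0)
        y = ref["s"].copy()
        y[ref.times >= 120.0] *= 0.5  # halve everything from the event on
        pert = Trajectory(ref.times, y[None, :], ["s"])
        d = response_delay(pert, ref, "s", 120.0)
        assert 0 <= d <= 40.0  # within about the first peak after the event

    def test_upward_departure_detected(self):
        ref = make_sine(t_end=1200.0, baseline=2.0)
        y = ref["s"].copy()
        y[ref.times >= 240.0] *= 1.6
        pert = Trajectory(ref.times, y[None, :], ["s"])
        d = response_delay(pert, ref, "s", 120.0)
        # the envelope interpolates between the last unchanged peak and
        # the first raised one, so the crossing lands between them
        assert 30.0 <= d <= 150.0
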