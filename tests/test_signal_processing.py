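import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorln import (
    FeatureSpec,
    SampledSignal,
    SpikeTrainSet,
    compute_feature,
    compute_psth,
    finite_difference,
    generate_spikes,
    half_wave_rectify,
    lowpass,
    peak_time,
)


def brute_force_psth_bins(spike_times, window, bin_size=0.1, step=0.025):
    """Independent oracle: enumerate every bin start and count spikes."""
    t_start, t_end = window
    starts = []
    s = t_start - bin_size + step
    while s < t_end - 1e-12:
        starts.append(s)
        s += step
    counts = [
        sum(1 for t in spike_times if s <= t < s + bin_size) for s in starts
    ]
    return np.asarray(starts), np.asarray(counts)


class TestPSTH:
    def test_no_spikes_gives_zero_rate(self):
        st_empty = SpikeTrainSet("osn", "none", [[], []], (0.0, 2.0))
        psth = compute_psth(st_empty)
        assert psth.units == "spike/s"
        np.testing.assert_allclose(psth.values, 0.0)

    def test_single_spike_occupies_four_bins_at_ten_hz(self):
        spikes = SpikeTrainSet("osn", "one", [[0.512]], (0.0, 1.0))
        psth = compute_psth(spikes)
        occupied = psth.values[psth.values > 0]
        assert occupied.size == 4
        np.testing.assert_allclose(occupied, 10.0)
        # agreement with brute-force bin enumeration
        starts, counts = brute_force_psth_bins([0.512], (0.0, 1.0))
        np.testing.assert_allclose(psth.values, counts / 0.1, atol=1e-12)
        np.testing.assert_allclose(psth.times, starts + 0.05, atol=1e-12)

    def test_each_spike_counted_bin_per_step_times(self):
        trains = [[0.21, 0.515, 0.88], [0.33, 0.77]]
        spikes = SpikeTrainSet("osn", "few", trains, (0.0, 1.5))
        psth = compute_psth(spikes)
        total = psth.values.sum() * 2 * 0.1  # n_trials * bin_size
        assert total == pytest.approx(4 * 5)  # 4 bins per spike, 5 spikes

    def test_constant_rate_recovered(self):
        rate = SampledSignal(0.0, 0.001, np.full(2001, 120.0), units="spike/s")
        spikes = generate_spikes(rate, 100, seed=3)
        psth = compute_psth(spikes)
        inner = psth.window(0.2, 1.8).values
        assert abs(inner.mean() - 120.0) < 3.0

    def test_preconditions(self):
        spikes = SpikeTrainSet("x", "y", [[0.5]], (0.0, 1.0))
        with pytest.raises(ValueError):
            compute_psth(SpikeTrainSet("x", "y", [], (0.0, 1.0)))
        with pytest.raises(ValueError):
            compute_psth(spikes, bin_size=0.1, overlap=0.1)


class TestFiniteDifference:
    def test_quadratic_closed_form(self):
        # x = a t^2 -> forward difference 2 a t + a * delta, exactly
        a, delta = 3.0, 0.05
        t = 0.01 * np.arange(400)
        sig = SampledSignal(0.0, 0.01, a * t ** 2, units="ppm")
        fd = finite_difference(sig, delta)
        np.testing.assert_allclose(
            fd.values, 2 * a * fd.times + a * delta, rtol=1e-12, atol=1e-12
        )
        assert fd.units == "ppm/s"
        assert fd.n == sig.n - 5

    def test_sine_phase_advanced_by_half_pi(self):
        t = 0.001 * np.arange(10000)
        sig = SampledSignal(0.0, 0.001, np.sin(2 * np.pi * t), units="ppm")
        fd = finite_difference(sig, 0.001)
        # projection-based phase of in/out at 1 Hz
        tt = fd.times
        def phase(v):
            return np.arctan2(v @ np.cos(2 * np.pi * tt), v @ np.sin(2 * np.pi * tt))
        advance = phase(fd.values) - phase(sig.values[: fd.n])
        assert advance == pytest.approx(np.pi / 2, rel=0.01)

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        seed=st.integers(0, 2 ** 16),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = SampledSignal(0.0, 0.01, rng.normal(size=50), units="ppm")
        y = SampledSignal(0.0, 0.01, rng.normal(size=50), units="ppm")
        combo = SampledSignal(0.0, 0.01, a * x.values + b * y.values, units="ppm")
        lhs = finite_difference(combo, 0.03).values
        rhs = (a * finite_difference(x, 0.03).values
               + b * finite_difference(y, 0.03).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_zero_pad_edge_mode(self):
        sig = SampledSignal(0.0, 0.01, np.arange(10, dtype=float), units="ppm")
        fd = finite_difference(sig, 0.02, edge="pad")
        assert fd.n == sig.n
        np.testing.assert_allclose(fd.values[-2:], 0.0)

    def test_preconditions(self):
        sig = SampledSignal(0.0, 0.01, np.arange(10, dtype=float), units="ppm")
        with pytest.raises(ValueError):
            finite_difference(sig, 0.015)  # not a multiple
        with pytest.raises(ValueError):
            finite_difference(sig, 0.2)  # exceeds span


class TestLowpass:
    def make_tone(self, freq, fs=1000.0, dur=4.0):
        t = np.arange(int(dur * fs)) / fs
        return SampledSignal(0.0, 1 / fs, np.sin(2 * np.pi * freq * t), units="ppm")

    def test_dc_preserved(self):
        sig = SampledSignal(0.0, 0.001, np.full(1000, 3.7), units="ppm")
        out = lowpass(sig, 20.0)
        assert out.n == sig.n
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-9)

    def test_passband_attenuation_below_five_percent(self):
        sig = self.make_tone(2.0)
        out = lowpass(sig, 20.0)
        inner = slice(500, -500)
        ratio = np.abs(out.values[inner]).max() / np.abs(sig.values[inner]).max()
        assert ratio > 0.95

    def test_stopband_attenuation_above_eighty_percent(self):
        sig = self.make_tone(80.0)
        out = lowpass(sig, 20.0)
        inner = slice(500, -500)
        ratio = np.abs(out.values[inner]).max() / np.abs(sig.values[inner]).max()
        assert ratio < 0.2

    def test_idempotent_in_passband(self):
        sig = self.make_tone(1.0)
        once = lowpass(sig, 20.0)
        twice = lowpass(once, 20.0)
        inner = slice(500, -500)
        delta = np.abs(twice.values[inner] - once.values[inner]).max()
        assert delta < 0.01 * np.abs(once.values[inner]).max()

    def test_cutoff_above_nyquist_rejected(self):
        sig = self.make_tone(1.0, fs=100.0)
        with pytest.raises(ValueError):
            lowpass(sig, 60.0)


class TestFeatures:
    def test_amplitude_of_constant_is_constant(self):
        sig = SampledSignal(0.0, 0.001, np.full(3000, 12.0), units="ppm")
        out = compute_feature(sig, FeatureSpec.for_kind("odor", "amplitude"))
        np.testing.assert_allclose(out.values, 12.0, rtol=1e-9)

    def test_parabola_acceleration_constant_over_rise(self):
        from odorln import WaveformSpec, generate_waveform
        spec = WaveformSpec("parabola", 0.5, 2.0, 100.0)  # 25 (t-0.5)^2
        sig = generate_waveform(spec, 0.001, 3.0)
        acc = compute_feature(sig, FeatureSpec.for_kind("odor", "acceleration"))
        mid = acc.window(1.0, 2.0).values
        np.testing.assert_allclose(mid, 50.0, rtol=0.05)
        assert acc.units == "ppm/s^2"

    def test_triangle_rate_of_change_steps_up_then_down(self, triangle_signal):
        roc = compute_feature(
            triangle_signal, FeatureSpec.for_kind("odor", "rate_of_change")
        )
        up = roc.window(0.7, 1.3).values
        down = roc.window(1.7, 2.3).values
        np.testing.assert_allclose(up, 20.0, rtol=0.05)
        np.testing.assert_allclose(down, -20.0, rtol=0.05)


class TestRectifyAndPeaks:
    def test_rectification(self):
        sig = SampledSignal(0.0, 0.01, np.array([-2.0, -0.1, 0.0, 0.5, 3.0]))
        out = half_wave_rectify(sig)
        np.testing.assert_allclose(out.values, [0, 0, 0, 0.5, 3.0])

    def test_peak_of_triangle(self, triangle_signal):
        assert peak_time(triangle_signal, (0.3, 2.7)) == pytest.approx(1.5)

    def test_derivative_cascade_advances_peaks(self, triangle_signal):
        d1 = half_wave_rectify(finite_difference(triangle_signal, 0.05))
        d2 = half_wave_rectify(finite_difference(d1, 0.05))
        w = (0.3, 2.4)
        t0 = peak_time(triangle_signal, w)
        t1 = peak_time(d1, w)
        t2 = peak_time(d2, w)
        assert t2 < t1 < t0

    def test_rectified_triangle_derivative_zeroes_falling_phase(self, triangle_signal):
        d1 = half_wave_rectify(finite_difference(triangle_signal, 0.05))
        falling = d1.window(1.6, 2.4).values
        np.testing.assert_allclose(falling, 0.0)

    def test_empty_window_rejected(self, triangle_signal):
        with pytest.raises(ValueError):
            peak_time(triangle_signal, (5.0, 6.0))
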