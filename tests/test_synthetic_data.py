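import numpy as np
import pytest

from odorln import (
    GroundTruthNonlinearity,
    OSNEncoderParams,
    WaveformSpec,
    design_parabola_ensemble,
    finite_difference,
    generate_spikes,
    generate_waveform,
    osn_encode,
    peak_time,
    pn_encode,
)
from odorln.signals import SampledSignal


class TestWaveforms:
    def test_ramp_finite_difference_equals_slope(self, ramp_signal):
        fd = finite_difference(ramp_signal, 0.001)
        t = fd.times
        rising = (t > 0.51) & (t < 2.49)
        np.testing.assert_allclose(fd.values[rising], 10.0, rtol=1e-9)

    def test_parabola_quarter_amplitude_at_half_rise(self):
        spec = WaveformSpec("parabola", 0.0, 2.0, 100.0)
        sig = generate_waveform(spec, 0.001, 2.0)
        assert sig.value_at(np.array([1.0]))[0] == pytest.approx(25.0)
        assert sig.value_at(np.array([2.0]))[0] == pytest.approx(100.0)

    def test_triangle_symmetric_about_midpoint_peak(self, triangle_signal):
        v = triangle_signal.window(0.5, 2.5).values
        np.testing.assert_allclose(v, v[::-1], atol=1e-9)

    @pytest.mark.parametrize("shape", ["step", "ramp", "parabola", "triangle"])
    def test_baseline_outside_support(self, shape):
        pk = 1.5 if shape in ("triangle", "parabola") else None
        spec = WaveformSpec(shape, 1.0, 1.0, 30.0, peak_time=pk, baseline=2.0)
        sig = generate_waveform(spec, 0.001, 3.0)
        outside = (sig.times < 0.999) | (sig.times > 2.001)
        np.testing.assert_allclose(sig.values[outside], 2.0)

    def test_s_parabola_derivative_is_triangle(self):
        # parabola with peak_time: monotone rise whose derivative is a
        # triangle apexed at peak_time
        spec = WaveformSpec("parabola", 0.5, 2.0, 40.0, peak_time=1.3)
        sig = generate_waveform(spec, 0.001, 3.0)
        assert np.all(np.diff(sig.window(0.5, 2.5).values) >= -1e-12)
        fd = finite_difference(sig, 0.001)
        assert peak_time(fd, (0.6, 2.4)) == pytest.approx(1.3, abs=0.002)
        # second difference piecewise constant on each phase
        fd2 = finite_difference(fd, 0.001)
        up = fd2.window(0.6, 1.2).values
        down = fd2.window(1.4, 2.3).values
        np.testing.assert_allclose(up, up[0], atol=1e-6)
        np.testing.assert_allclose(down, down[0], atol=1e-6)
        assert up[0] > 0 > down[0]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec("sine", 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            WaveformSpec("step", 0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            WaveformSpec("triangle", 0.0, 1.0, 1.0, peak_time=2.0)
        spec = WaveformSpec("step", 0.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            generate_waveform(spec, 0.001, 2.0)  # support exceeds duration


class TestOSNEncoder:
    def test_zero_stimulus_gives_spontaneous_rate(self):
        odor = SampledSignal(0.0, 0.001, np.zeros(2000), units="ppm")
        rate = osn_encode(odor, OSNEncoderParams(baseline_rate=7.0))
        np.testing.assert_allclose(rate.values, 7.0)

    def test_ramp_input_yields_step_output_for_pure_roc_encoder(self, ramp_signal):
        # ramp slope 10 ppm/s, rate-of-change gain 3 -> plateau at 5 + 30
        params = OSNEncoderParams(gain_amp=0.0, gain_roc=3.0, baseline_rate=5.0)
        rate = osn_encode(ramp_signal, params)
        t = rate.times
        plateau = (t > 0.55) & (t < 2.4)
        np.testing.assert_allclose(rate.values[plateau], 35.0, rtol=1e-9)

    def test_parabola_input_yields_ramp_output_for_pure_roc_encoder(self):
        spec = WaveformSpec("parabola", 0.0, 2.0, 100.0)  # x = 25 t^2
        odor = generate_waveform(spec, 0.001, 2.0)
        params = OSNEncoderParams(gain_amp=0.0, gain_roc=1.0, baseline_rate=0.0,
                                  roc_delta=0.010)
        rate = osn_encode(odor, params)
        # forward difference of 25 t^2 at interval D is 50 t + 25 D
        t = rate.times
        inside = (t > 0.1) & (t < 1.8)
        np.testing.assert_allclose(
            rate.values[inside], 50 * t[inside] + 25 * 0.010, rtol=1e-9
        )

    def test_rate_of_change_contribution_scales_with_slope(self):
        params = OSNEncoderParams(gain_amp=0.0, gain_roc=2.0, baseline_rate=0.0,
                                  max_rate=1e6)
        rates = []
        for amp in (10.0, 20.0):
            ramp = generate_waveform(WaveformSpec("ramp", 0.0, 2.0, amp), 0.001, 2.0)
            r = osn_encode(ramp, params)
            rates.append(np.median(r.window(0.5, 1.5).values))
        assert rates[1] == pytest.approx(2 * rates[0], rel=1e-9)


class TestEnsembleDesign:
    def test_empty_target_list(self):
        assert design_parabola_ensemble([], OSNEncoderParams(gain_amp=0.0)) == []

    def test_amplitude_gain_not_invertible(self):
        tri = WaveformSpec("triangle", 0.5, 2.0, 100.0, peak_time=1.5, baseline=5.0)
        with pytest.raises(ValueError):
            design_parabola_ensemble([tri], OSNEncoderParams(gain_amp=0.5))

    def test_round_trip_reproduces_triangle_rate(self):
        params = OSNEncoderParams(gain_amp=0.0, gain_roc=3.0, baseline_rate=5.0,
                                  roc_delta=0.010)
        tri = WaveformSpec("triangle", 0.5, 2.0, 120.0, peak_time=1.2, baseline=5.0)
        (odor_spec,) = design_parabola_ensemble([tri], params)
        odor = generate_waveform(odor_spec, 0.002, 4.0)
        rate = osn_encode(odor, params)
        target = generate_waveform(tri, 0.002, 4.0)
        grid = rate.window(0.55, 2.4).times
        resid = rate.value_at(grid) - target.value_at(grid)
        # exact up to the O(roc_delta) forward-difference discretisation
        slope = (120.0 - 5.0) / 0.7
        assert np.max(np.abs(resid)) < slope * params.roc_delta


class TestPNStage:
    def test_constant_input_reads_nonlinearity_at_zero_derivative(self):
        truth = GroundTruthNonlinearity()
        y = SampledSignal(0.0, 0.005, np.full(1000, 80.0), units="spike/s")
        z = pn_encode(y, truth)
        np.testing.assert_allclose(z.values, float(truth(80.0, 0.0)), rtol=1e-9)

    def test_triangle_input_peak_advanced(self, triangle_signal):
        y = triangle_signal.copy(units="spike/s")
        z = pn_encode(y, GroundTruthNonlinearity())
        assert peak_time(z, (0.3, 2.4)) < peak_time(y, (0.3, 2.4))

    def test_identity_nonlinearity_reproduces_input(self):
        y = SampledSignal(0.0, 0.005, 50 + 20 * np.sin(np.arange(800) * 0.02),
                          units="spike/s")
        z = pn_encode(y, lambda yy, dd: yy)
        np.testing.assert_allclose(z.values, y.values[: z.n], rtol=1e-12)

    def test_ground_truth_invariants(self):
        truth = GroundTruthNonlinearity()
        y = np.linspace(0, 150, 31)
        d = np.linspace(-400, 400, 41)
        Y, D = np.meshgrid(y, d, indexing="ij")
        Z = truth(Y, D)
        assert np.all(Z >= 0)
        # flat for negative derivatives at fixed y
        neg = Z[:, d < 0]
        np.testing.assert_allclose(neg - neg[:, :1], 0.0, atol=1e-12)
        # nondecreasing in positive d; gain nonincreasing in y
        pos = Z[:, d > 0]
        assert np.all(np.diff(pos, axis=1) >= -1e-12)
        beta = truth.beta(y)
        assert np.all(np.diff(beta) < 0)


class TestSpikes:
    def test_zero_rate_gives_no_spikes(self):
        rate = SampledSignal(0.0, 0.01, np.zeros(100), units="spike/s")
        st = generate_spikes(rate, 5, seed=0)
        assert st.total_spikes == 0

    def test_constant_rate_mean_count(self):
        rate = SampledSignal(0.0, 0.001, np.full(1001, 100.0), units="spike/s")
        st = generate_spikes(rate, 200, seed=42)
        counts = np.array([t.size for t in st.trials])
        se = np.sqrt(100.0 / 200)
        assert abs(counts.mean() - 100.0) < 3 * se

    def test_fano_factor_near_one(self):
        rate = SampledSignal(0.0, 0.001, np.full(1001, 80.0), units="spike/s")
        st = generate_spikes(rate, 400, seed=7)
        counts = np.array([t.size for t in st.trials])
        fano = counts.var() / counts.mean()
        assert 0.75 < fano < 1.25

    def test_seed_determinism(self):
        rate = SampledSignal(0.0, 0.005, np.full(400, 60.0), units="spike/s")
        a = generate_spikes(rate, 3, seed=11)
        b = generate_spikes(rate, 3, seed=11)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta, tb)

    def test_negative_rate_rejected(self):
        rate = SampledSignal(0.0, 0.01, np.array([1.0, -0.5, 1.0]), units="spike/s")
        with pytest.raises(ValueError):
            generate_spikes(rate, 1, seed=0)
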