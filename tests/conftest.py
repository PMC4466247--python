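import numpy as np
import pytest

from odorln import SampledSignal, WaveformSpec, generate_waveform


@pytest.fixture
def triangle_signal() -> SampledSignal:
    """Symmetric 20-ppm triangle peaking at 1.5 s, sampled at 1 ms."""
    spec = WaveformSpec("triangle", 0.5, 2.0, 20.0, peak_time=1.5)
    return generate_waveform(spec, 0.001, 3.0)


@pytest.fixture
def ramp_signal() -> SampledSignal:
    """Ramp from 0 to 20 ppm over 2 s (slope 10 ppm/s), sampled at 1 ms."""
    spec = WaveformSpec("ramp", 0.5, 2.0, 20.0)
    return generate_waveform(spec, 0.001, 3.0)


def make_signal(values, period=0.01, t0=0.0, units="spike/s") -> SampledSignal:
    return SampledSignal(t0=t0, sample_period=period,
                         values=np.asarray(values, float), units=units)
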