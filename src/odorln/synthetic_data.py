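"""Synthetic odor stimuli, OSN/PN rates, and Poisson spike trains.

This module generates the synthetic world every downstream stage is
tested on, with the statistical structure the analysis assumes:

* piecewise-polynomial odor waveforms — step pulses, ramps, parabolas
  and triangles, plus the monotone piecewise-quadratic ("S-parabola")
  concentration profile whose time derivative is a triangle;
* a minimal phenomenological OSN encoder responding to the odor
  concentration and its half-wave-rectified rate of change (the two
  features first-order olfactory neurons are known to represent);
* an analytic inversion of that encoder that designs the parabola odor
  ensemble inducing a prescribed set of triangle-shaped OSN rates;
* a ground-truth 2D PN nonlinearity f*(y, dy/dt) with half-wave
  rectified rate-of-change drive whose gain decays with amplitude;
* inhomogeneous-Poisson spike generation by thinning, for trial-to-trial
  variability.

The OSN stage is deliberately not a biophysical transduction model:
the downstream analyses only require realistic response *shapes*
(step output to a ramp input, ramp output to a parabola input), which
the amplitude + rectified-rate-of-change form reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .signal_processing import FeatureSpec, compute_feature, finite_difference
from .signals import SampledSignal, SpikeTrainSet

__all__ = [
    "WaveformSpec",
    "OSNEncoderParams",
    "GroundTruthNonlinearity",
    "generate_waveform",
    "osn_encode",
    "design_parabola_ensemble",
    "pn_encode",
    "generate_spikes",
]


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformSpec:
    """Piecewise-polynomial stimulus description.

    shape
        ``step``     — constant ``peak_amplitude`` over the support.
        ``ramp``     — linear rise from baseline to ``peak_amplitude``
                       over the full support.
        ``parabola`` — without ``peak_time``: quadratic rise
                       ``baseline + c (t - onset)^2`` reaching the peak
                       at the end of the support.  With ``peak_time``:
                       monotone piecewise-quadratic whose derivative is
                       a triangle peaking at ``peak_time`` (the exact
                       inverse image of a triangle rate under a pure
                       rate-of-change encoder).
        ``triangle`` — linear rise to ``peak_amplitude`` at
                       ``peak_time``, then linear fall back to baseline.

    The signal equals ``baseline`` outside
    ``[onset_time, onset_time + duration]``.
    """

    shape: str
    onset_time: float
    duration: float
    peak_amplitude: float
    peak_time: float | None = None
    baseline: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("step", "ramp", "parabola", "triangle"):
            raise ValueError(f"unsupported shape {self.shape!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be nonnegative")
        if self.shape == "triangle" and self.peak_time is None:
            raise ValueError("triangle requires peak_time")
        if self.peak_time is not None:
            if not (self.onset_time <= self.peak_time <= self.onset_time + self.duration):
                raise ValueError("peak_time must lie within the stimulus support")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration


def generate_waveform(
    spec: WaveformSpec,
    sample_period: float,
    total_duration: float,
) -> SampledSignal:
    """Sample the exact piecewise polynomial on a uniform grid from t = 0."""
    if sample_period <= 0:
        raise ValueError("sample_period must be positive")
    if spec.offset_time > total_duration + 1e-12:
        raise ValueError("stimulus support exceeds total_duration")
    n = int(round(total_duration / sample_period)) + 1
    t = sample_period * np.arange(n)
    x = np.full(n, spec.baseline, dtype=float)
    on, dur, a = spec.onset_time, spec.duration, spec.peak_amplitude
    inside = (t >= on - 1e-12) & (t <= on + dur + 1e-12)
    s = t[inside] - on

    if spec.shape == "step":
        x[inside] = a
    elif spec.shape == "ramp":
        x[inside] = spec.baseline + (a - spec.baseline) * s / dur
    elif spec.shape == "triangle":
        rise = spec.peak_time - on
        fall = dur - rise
        up = s <= rise + 1e-12
        y = np.empty_like(s)
        y[up] = spec.baseline + (a - spec.baseline) * (s[up] / rise if rise > 0 else 1.0)
        y[~up] = spec.baseline + (a - spec.baseline) * ((dur - s[~up]) / fall if fall > 0 else 0.0)
        x[inside] = y
    elif spec.shape == "parabola":
        if spec.peak_time is None:
            x[inside] = spec.baseline + (a - spec.baseline) * (s / dur) ** 2
        else:
            # monotone S-curve: derivative is a triangle with apex at peak_time,
            # total area (amplitude gain) = a - baseline
            rise = spec.peak_time - on
            fall = dur - rise
            amp = a - spec.baseline
            d_peak = 2.0 * amp / dur  # peak slope so the area is amp
            y = np.empty_like(s)
            up = s <= rise + 1e-12
            if rise > 0:
                y[up] = 0.5 * d_peak * s[up] ** 2 / rise
            else:
                y[up] = 0.0
            if fall > 0:
                sd = s[~up] - rise
                y[~up] = 0.5 * d_peak * rise + d_peak * sd - 0.5 * d_peak * sd ** 2 / fall
            else:
                y[~up] = amp
            x[inside] = spec.baseline + y
    return SampledSignal(t0=0.0, sample_period=sample_period, values=x, units="ppm")


# ---------------------------------------------------------------------------
# OSN encoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OSNEncoderParams:
    """Minimal amplitude + rectified-rate-of-change OSN model.

    rate(t) = clip(baseline_rate + gain_amp * x(t)
                   + gain_roc * max(dx/dt, 0), 0, max_rate)

    with dx/dt the forward difference of the concentration at interval
    ``roc_delta``.
    """

    gain_amp: float = 0.5       # (spike/s) per ppm
    gain_roc: float = 3.0       # (spike/s) per (ppm/s)
    baseline_rate: float = 5.0  # spike/s
    max_rate: float = 300.0     # spike/s
    roc_delta: float = 0.050    # s

    def __post_init__(self) -> None:
        if not self.max_rate > self.baseline_rate >= 0:
            raise ValueError("require max_rate > baseline_rate >= 0")
        if self.roc_delta <= 0:
            raise ValueError("roc_delta must be positive")


def osn_encode(odor: SampledSignal, params: OSNEncoderParams) -> SampledSignal:
    """OSN spike rate in response to an odor concentration trace.

    The output is shortened by ``roc_delta`` at the trailing edge (the
    forward difference has no lookahead there).
    """
    deriv = finite_difference(odor, params.roc_delta, edge="drop")
    amp = odor.values[: deriv.n]
    rate = (
        params.baseline_rate
        + params.gain_amp * amp
        + params.gain_roc * np.maximum(deriv.values, 0.0)
    )
    return SampledSignal(
        t0=odor.t0,
        sample_period=odor.sample_period,
        values=np.clip(rate, 0.0, params.max_rate),
        units="spike/s",
    )


def design_parabola_ensemble(
    target_triangles: list[WaveformSpec],
    params: OSNEncoderParams,
) -> list[WaveformSpec]:
    """Odor waveforms that induce prescribed triangle-shaped OSN rates.

    For a pure rate-of-change encoder (``gain_amp = 0``) the inversion
    is analytic: the concentration must be the running integral of
    ``(rate - baseline_rate) / gain_roc``, i.e. the monotone
    piecewise-quadratic S-parabola whose derivative is the target
    triangle.  The discontinuous return to baseline after the stimulus
    produces a negative derivative which the encoder rectifies away, so
    the round trip is exact on both phases up to the O(roc_delta)
    forward-difference discretisation.

    Raises
    ------
    ValueError
        If ``gain_amp != 0`` (the inverse is then a linear ODE with no
        WaveformSpec representation) or a target dips below the
        encoder's spontaneous rate (nonnegative concentration slope
        cannot lower the rate).
    """
    if params.gain_roc <= 0:
        raise ValueError("encoder must have gain_roc > 0 to be invertible")
    if params.gain_amp != 0:
        raise ValueError("analytic ensemble design requires a pure rate-of-change encoder (gain_amp = 0)")
    specs = []
    for tri in target_triangles:
        if tri.shape != "triangle":
            raise ValueError("targets must be triangle waveforms")
        if tri.baseline < params.baseline_rate - 1e-9:
            raise ValueError("target baseline below the encoder's spontaneous rate")
        if tri.peak_amplitude > params.max_rate:
            raise ValueError("target peak exceeds the encoder's max_rate")
        # area under (rate - baseline_rate)/gain_roc = final concentration
        excess = tri.peak_amplitude - tri.baseline
        amp = 0.5 * excess * tri.duration / params.gain_roc
        specs.append(
            WaveformSpec(
                shape="parabola",
                onset_time=tri.onset_time,
                duration=tri.duration,
                peak_amplitude=amp,
                peak_time=tri.peak_time,
                baseline=0.0,
                label=f"odor_for_{tri.label}" if tri.label else "",
            )
        )
    return specs


# ---------------------------------------------------------------------------
# PN ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthNonlinearity:
    """Closed-form PN nonlinearity f*(y, dy/dt) used to synthesise PN rates.

    f*(y, d) = clip(base_rate + gain_amp * y
                    + gain_roc * exp(-gain_decay_constant * y) * max(d, 0),
                    0, max_rate)

    The rate-of-change drive is half-wave rectified, and its gain
    ``beta(y) = gain_roc * exp(-gain_decay_constant * y)`` decays with the
    input amplitude — the amplitude-dependent gain observed in PNs.
    """

    base_rate: float = 5.0              # spike/s
    gain_amp: float = 0.25              # dimensionless (spike/s per spike/s)
    gain_roc: float = 1.1               # s (spike/s per spike/s^2)
    gain_decay_constant: float = 0.008  # (spike/s)^-1
    max_rate: float = 300.0             # spike/s

    def beta(self, y: np.ndarray) -> np.ndarray:
        """Conditional rate-of-change gain at amplitude y."""
        return self.gain_roc * np.exp(-self.gain_decay_constant * np.asarray(y, float))

    def __call__(self, y: np.ndarray, dydt: np.ndarray) -> np.ndarray:
        y = np.asarray(y, float)
        z = (
            self.base_rate
            + self.gain_amp * y
            + self.beta(y) * np.maximum(np.asarray(dydt, float), 0.0)
        )
        return np.clip(z, 0.0, self.max_rate)


def pn_encode(
    osn_rate: SampledSignal,
    truth: GroundTruthNonlinearity | Callable,
    feature: FeatureSpec | None = None,
) -> SampledSignal:
    """PN spike rate z(t) = f*(y(t), dy/dt(t)) from an OSN rate trace.

    dy/dt is derived with the OSN feature defaults (4 Hz low-pass,
    100-ms forward difference) unless another spec is given; the output
    is restricted to the derivative's support.
    """
    feature = feature or FeatureSpec.for_kind("osn", "rate_of_change")
    deriv = compute_feature(osn_rate, FeatureSpec(
        "rate_of_change", feature.signal_kind, feature.delta_roc,
        feature.delta_acc, feature.cutoff_amp, feature.cutoff_roc,
    ))
    y = osn_rate.values[: deriv.n]
    z = np.maximum(np.asarray(truth(y, deriv.values), float), 0.0)
    return SampledSignal(
        t0=osn_rate.t0,
        sample_period=osn_rate.sample_period,
        values=z,
        units="spike/s",
    )


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def generate_spikes(
    rate: SampledSignal,
    n_trials: int,
    seed: int,
    neuron_label: str = "",
    stimulus_label: str = "",
) -> SpikeTrainSet:
    """Inhomogeneous Poisson spike trains by thinning.

    Candidate spikes are drawn from a homogeneous Poisson process at the
    peak rate and retained with probability rate(t)/peak.  The expected
    count per trial is the integral of the rate over the support;
    identical seeds give identical output.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if np.any(rate.values < 0):
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    t_start, t_end = rate.t0, rate.t_end
    span = t_end - t_start
    r_max = float(rate.values.max())
    trials = []
    for _ in range(n_trials):
        if r_max <= 0 or span <= 0:
            trials.append(np.empty(0))
            continue
        n_cand = rng.poisson(r_max * span)
        cand = np.sort(rng.uniform(t_start, t_end, n_cand))
        keep = rng.uniform(0.0, r_max, n_cand) < rate.value_at(cand)
        kept = cand[keep]
        # strictly increasing: drop exact duplicates (measure-zero event)
        if kept.size > 1:
            kept = kept[np.concatenate([[True], np.diff(kept) > 0])]
        trials.append(kept)
    return SpikeTrainSet(
        neuron_label=neuron_label,
        stimulus_label=stimulus_label,
        trials=trials,
        recording_window=(t_start, t_end),
    )
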