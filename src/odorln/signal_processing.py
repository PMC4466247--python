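"""Spike-rate estimation and amplitude / rate-of-change / acceleration features.

Rates are estimated with an overlapping-bin peristimulus-time histogram
(100-ms bins advancing by 25 ms at the defaults).  Derivatives use the
forward difference ``dx/dt = [x(t+Delta) - x(t)] / Delta`` with a stage-
specific interval Delta, applied after a zero-phase low-pass filter so
that high-frequency noise does not dominate the difference:

=======================  =======  ==============
quantity                 Delta    low-pass input
=======================  =======  ==============
odor rate of change      50 ms    20 Hz (amplitude)
odor acceleration        100 ms   10 Hz (rate of change)
OSN rate of change       100 ms   4 Hz (spike rate)
OSN acceleration         100 ms   4 Hz (rate of change)
=======================  =======  ==============

The filter is a 2nd-order Butterworth applied forward and backward
(zero-phase), because phase distortion would corrupt the peak-time
analysis downstream; the design cutoff is pre-warped so the -3 dB point
of the *two-pass* response sits at the requested frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy import signal as sps

from .signals import SampledSignal, SpikeTrainSet, differentiate_units


@lru_cache(maxsize=1)
def _load_default_table() -> dict:
    text = resources.files(__package__).joinpath("feature_defaults.yaml").read_text()
    return yaml.safe_load(text)

__all__ = [
    "FeatureSpec",
    "ODOR_FEATURE_DEFAULTS",
    "OSN_FEATURE_DEFAULTS",
    "compute_psth",
    "finite_difference",
    "lowpass",
    "compute_feature",
    "half_wave_rectify",
    "peak_time",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Recipe for deriving one input feature from a signal.

    Parameters
    ----------
    feature : {"amplitude", "rate_of_change", "acceleration"}
    signal_kind : {"odor", "osn"}
        Selects the default difference intervals and filter cutoffs.
    delta_roc, delta_acc : float
        Forward-difference intervals (s) for the first and second
        derivative stages.
    cutoff_amp, cutoff_roc : float
        Low-pass cutoffs (Hz) applied to the amplitude before the first
        difference and to the rate of change before the second.
    """

    feature: str = "amplitude"
    signal_kind: str = "odor"
    delta_roc: float = 0.050
    delta_acc: float = 0.100
    cutoff_amp: float = 20.0
    cutoff_roc: float = 10.0

    def __post_init__(self) -> None:
        if self.feature not in ("amplitude", "rate_of_change", "acceleration"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.signal_kind not in ("odor", "osn"):
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        if min(self.delta_roc, self.delta_acc) <= 0:
            raise ValueError("difference intervals must be positive")
        if min(self.cutoff_amp, self.cutoff_roc) <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def for_kind(cls, signal_kind: str, feature: str = "amplitude") -> "FeatureSpec":
        """Defaults per stage: odor (50/100 ms, 20/10 Hz), OSN (100/100 ms, 4/4 Hz).

        Read from the packaged ``feature_defaults.yaml`` table.
        """
        table = _load_default_table()
        if signal_kind not in table:
            raise ValueError(f"unknown signal_kind {signal_kind!r}")
        return cls(feature, signal_kind, **table[signal_kind])


ODOR_FEATURE_DEFAULTS = FeatureSpec.for_kind("odor")
OSN_FEATURE_DEFAULTS = FeatureSpec.for_kind("osn")


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def compute_psth(
    spikes: SpikeTrainSet,
    bin_size: float = 0.100,
    overlap: float = 0.075,
) -> SampledSignal:
    """Trial-averaged spike rate from overlapping bins.

    Bins of width ``bin_size`` advance by ``bin_size - overlap`` (25 ms
    at the defaults).  Every bin that intersects the recording window is
    evaluated, so each interior spike is counted exactly
    ``bin_size / step`` times across bins.  The value of a bin is

        count across trials / (n_trials * bin_size)     [spike/s]

    timestamped at the bin centre (half-open bins ``[start, start+bin)``).
    """
    if spikes.n_trials == 0:
        raise ValueError("empty trial set")
    if overlap >= bin_size:
        raise ValueError("overlap must be smaller than bin_size")
    if overlap < 0:
        raise ValueError("overlap must be nonnegative")
    step = bin_size - overlap
    t_start, t_end = spikes.recording_window

    # first bin: the earliest one overlapping the window; last bin: start < t_end
    k0 = -int(np.ceil(bin_size / step)) + 1
    n_bins = int(np.floor((t_end - t_start) / step - 1e-9)) + 1 - k0
    starts = t_start + step * (np.arange(n_bins) + k0)

    all_spikes = (
        np.concatenate([t for t in spikes.trials if t.size])
        if spikes.total_spikes
        else np.empty(0)
    )
    counts = np.zeros(n_bins)
    if all_spikes.size:
        # spike s falls in bins with start in (s - bin_size, s]
        lo = np.searchsorted(starts, all_spikes - bin_size, side="right")
        hi = np.searchsorted(starts, all_spikes, side="right")
        np.add.at(counts, np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]), 1)
    rates = counts / (spikes.n_trials * bin_size)
    return SampledSignal(
        t0=float(starts[0] + bin_size / 2),
        sample_period=step,
        values=rates,
        units="spike/s",
    )


# ---------------------------------------------------------------------------
# derivatives and filtering
# ---------------------------------------------------------------------------

def finite_difference(
    signal: SampledSignal,
    delta: float,
    edge: str = "drop",
) -> SampledSignal:
    """Forward difference ``[x(t + delta) - x(t)] / delta`` aligned to t.

    ``delta`` must be an integer multiple of the sample period.  Trailing
    samples with no lookahead are dropped (default) or zero-padded
    (``edge="pad"``).  Units are divided by seconds.
    """
    k = delta / signal.sample_period
    k_int = int(round(k))
    if abs(k - k_int) > 1e-6 or k_int < 1:
        raise ValueError("delta must be a positive integer multiple of sample_period")
    if k_int >= signal.n:
        raise ValueError("delta must be smaller than the signal span")
    diff = (signal.values[k_int:] - signal.values[:-k_int]) / delta
    if edge == "pad":
        diff = np.concatenate([diff, np.zeros(k_int)])
    elif edge != "drop":
        raise ValueError("edge must be 'drop' or 'pad'")
    return SampledSignal(
        t0=signal.t0,
        sample_period=signal.sample_period,
        values=diff,
        units=differentiate_units(signal.units),
    )


def lowpass(signal: SampledSignal, cutoff: float) -> SampledSignal:
    """Zero-phase 2nd-order Butterworth low-pass with -3 dB at ``cutoff``.

    The forward-backward application squares the magnitude response, so
    the design frequency is pre-warped by (sqrt(2) - 1)^(1/4) to place
    the overall half-power point at the requested cutoff.  A constant
    signal passes unchanged; output length equals input length.
    """
    fs = 1.0 / signal.sample_period
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    # |H|^4 = 1/2 at cutoff  =>  design wc = cutoff / (2^(1/2)-1)^(1/4)
    wc = cutoff / (2 ** 0.5 - 1) ** 0.25
    wc = min(wc, 0.999 * fs / 2)
    sos = sps.butter(2, wc, btype="low", fs=fs, output="sos")
    padlen = min(signal.n - 1, 3 * 10)
    filtered = sps.sosfiltfilt(sos, signal.values, padlen=padlen)
    return signal.copy(values=filtered)


def compute_feature(signal: SampledSignal, spec: FeatureSpec) -> SampledSignal:
    """Derive the amplitude, rate-of-change or acceleration signal.

    amplitude:       lowpass(x, cutoff_amp)
    rate_of_change:  FD(lowpass(x, cutoff_amp), delta_roc)
    acceleration:    FD(lowpass(rate_of_change, cutoff_roc), delta_acc)
    """
    amp = lowpass(signal, spec.cutoff_amp)
    if spec.feature == "amplitude":
        return amp
    roc = finite_difference(amp, spec.delta_roc)
    if spec.feature == "rate_of_change":
        return roc
    return finite_difference(lowpass(roc, spec.cutoff_roc), spec.delta_acc)


def half_wave_rectify(signal: SampledSignal) -> SampledSignal:
    """``max(value, 0)`` elementwise."""
    return signal.copy(values=np.maximum(signal.values, 0.0))


def peak_time(signal: SampledSignal, window: tuple) -> float:
    """Time of the maximum sample within ``window``; ties broken earliest."""
    sub = signal.window(*window)
    return float(sub.times[int(np.argmax(sub.values))])
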