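"""Core time-series containers and their plain-text serialisation.

Two in-memory types carry every signal through the pipeline:

``SampledSignal``
    A uniformly sampled trace — odor concentration (ppm), a spike rate
    (spike/s), or a derivative thereof — with an explicit start time,
    sample period and unit string.  All downstream joins are done on
    timestamps, never on array index, so signals whose edge samples were
    dropped by filtering or differencing still align correctly.

``SpikeTrainSet``
    Per-trial spike times (seconds) for one neuron under one stimulus.

On disk, traces are 2-column delimited text (``time_s``, value) with a
one-line header naming the units, and spike trains are 2-column text
(``trial_index``, ``spike_time_s``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SampledSignal",
    "SpikeTrainSet",
    "differentiate_units",
]

#: unit produced by one time differentiation of each known unit
_DERIV_UNITS = {
    "ppm": "ppm/s",
    "ppm/s": "ppm/s^2",
    "spike/s": "spike/s^2",
    "spike/s^2": "spike/s^3",
}


def differentiate_units(units: str) -> str:
    """Unit string after dividing by seconds once."""
    return _DERIV_UNITS.get(units, f"{units}/s")


@dataclass
class SampledSignal:
    """Uniformly sampled time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample, in seconds.
    sample_period : float
        Spacing between samples, in seconds (> 0).
    values : ndarray
        Sample amplitudes; finite.
    units : str
        Unit of the amplitudes, e.g. ``"ppm"`` or ``"spike/s"``.
    """

    t0: float
    sample_period: float
    values: np.ndarray
    units: str = "ppm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Timestamps of every sample."""
        return self.t0 + self.sample_period * np.arange(self.n)

    @property
    def t_end(self) -> float:
        """Timestamp of the last sample."""
        return self.t0 + self.sample_period * (self.n - 1)

    def copy(self, **overrides) -> "SampledSignal":
        kw = dict(
            t0=self.t0,
            sample_period=self.sample_period,
            values=self.values.copy(),
            units=self.units,
        )
        kw.update(overrides)
        return SampledSignal(**kw)

    # -- alignment ------------------------------------------------------
    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary times inside the support."""
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < self.t0 - 1e-12 or t.max() > self.t_end + 1e-12):
            raise ValueError("query times outside signal support")
        return np.interp(t, self.times, self.values)

    def window(self, t_lo: float, t_hi: float) -> "SampledSignal":
        """Sub-signal restricted to samples with t_lo <= t <= t_hi."""
        times = self.times
        mask = (times >= t_lo - 1e-12) & (times <= t_hi + 1e-12)
        if not mask.any():
            raise ValueError("window contains no samples")
        first = int(np.argmax(mask))
        return SampledSignal(
            t0=times[first],
            sample_period=self.sample_period,
            values=self.values[mask],
            units=self.units,
        )

    # -- i/o ------------------------------------------------------------
    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        """Write as 2-column delimited text with a units header."""
        data = np.column_stack([self.times, self.values])
        np.savetxt(
            path,
            data,
            delimiter=delimiter,
            header=f"time_s{delimiter}value_{self.units}",
            comments="",
            fmt="%.9g",
        )

    @classmethod
    def read(cls, path: str | Path, delimiter: str = "\t") -> "SampledSignal":
        with open(path) as fh:
            header = fh.readline().strip()
        units = header.split(delimiter)[1].removeprefix("value_")
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
        t = data[:, 0]
        if t.size < 2:
            raise ValueError("need at least two samples to infer sample period")
        period = float(np.median(np.diff(t)))
        return cls(t0=float(t[0]), sample_period=period, values=data[:, 1], units=units)


@dataclass
class SpikeTrainSet:
    """Per-trial spike times for one neuron under one stimulus.

    Invariants: every spike time lies inside ``recording_window`` and is
    strictly increasing within its trial.
    """

    neuron_label: str
    stimulus_label: str
    trials: list = field(default_factory=list)
    recording_window: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        t_start, t_end = self.recording_window
        if t_end <= t_start:
            raise ValueError("recording_window must have positive length")
        clean = []
        for trial in self.trials:
            arr = np.asarray(trial, dtype=float)
            if arr.size:
                if np.any(np.diff(arr) <= 0):
                    raise ValueError("spike times must be strictly increasing")
                if arr.min() < t_start or arr.max() > t_end:
                    raise ValueError("spike times outside recording_window")
            clean.append(arr)
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        rows = [
            (i, t)
            for i, trial in enumerate(self.trials)
            for t in trial
        ]
        with open(path, "w") as fh:
            fh.write(f"trial_index{delimiter}spike_time_s\n")
            for i, t in rows:
                fh.write(f"{i}{delimiter}{t:.9g}\n")

    @classmethod
    def read(
        cls,
        path: str | Path,
        recording_window: tuple,
        neuron_label: str = "",
        stimulus_label: str = "",
        n_trials: int | None = None,
        delimiter: str = "\t",
    ) -> "SpikeTrainSet":
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
        if data.size == 0:
            trials: list[Sequence[float]] = [[] for _ in range(n_trials or 0)]
        else:
            idx = data[:, 0].astype(int)
            k = max(idx.max() + 1, n_trials or 0)
            trials = [data[idx == i, 1] for i in range(k)]
        return cls(
            neuron_label=neuron_label,
            stimulus_label=stimulus_label,
            trials=trials,
            recording_window=recording_window,
        )
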