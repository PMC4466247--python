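"""Which stimulus features does each neural output represent?

The similarity between an input feature x (amplitude, rate of change or
acceleration of the odor or OSN signal) and an output y (OSN or PN spike
rate) is quantified by the zero-lag normalized cross-covariance

    rho(x, y) = (1/N) * sum_i (x[i] - mu_x) (y[i] - mu_y) / (sigma_x sigma_y)

with population standard deviations.  Per replicate ("fly"), the samples
from the whole stimulus battery are pooled by concatenation before
correlating; summaries report mean +/- sd of rho across replicates and a
two-sample t-test between feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_processing import FeatureSpec, compute_feature
from .signals import SampledSignal

__all__ = [
    "CorrelationResult",
    "cross_correlation_coefficient",
    "aligned_samples",
    "feature_correlation_table",
    "compare_correlations",
]


@dataclass
class CorrelationResult:
    """Correlation of one input feature with one output, over replicates."""

    input_feature: str
    output_label: str
    rho: float                      # pooled-replicate mean
    n_samples: int
    per_fly_rhos: list = field(default_factory=list)

    @property
    def rho_mean(self) -> float:
        return float(np.mean(self.per_fly_rhos)) if self.per_fly_rhos else self.rho

    @property
    def rho_sd(self) -> float:
        return float(np.std(self.per_fly_rhos, ddof=1)) if len(self.per_fly_rhos) > 1 else 0.0


def cross_correlation_coefficient(x, y) -> float:
    """Zero-lag normalized cross-covariance of two aligned sample vectors.

    Accepts raw arrays (already aligned) or two ``SampledSignal``s, which
    are resampled onto the intersection of their supports first.
    """
    if isinstance(x, SampledSignal) and isinstance(y, SampledSignal):
        x, y = aligned_samples(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the signals")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def aligned_samples(
    x: SampledSignal,
    y: SampledSignal,
    window: tuple | None = None,
) -> tuple:
    """Resample two signals onto a common grid over their overlap.

    The grid is the coarser signal's timestamps restricted to the
    intersection of the two supports (and ``window`` if given); the finer
    signal is linearly interpolated onto it.
    """
    t_lo = max(x.t0, y.t0)
    t_hi = min(x.t_end, y.t_end)
    if window is not None:
        t_lo = max(t_lo, window[0])
        t_hi = min(t_hi, window[1])
    if t_hi <= t_lo:
        raise ValueError("signals have empty overlap")
    coarse, fine = (x, y) if x.sample_period >= y.sample_period else (y, x)
    grid = coarse.window(t_lo, t_hi).times
    xv = x.value_at(grid)
    yv = y.value_at(grid)
    return xv, yv


def feature_correlation_table(
    input_signal,
    outputs,
    feature_specs,
    window: tuple | None = None,
) -> list:
    """One CorrelationResult per (feature, output) pair.

    Parameters
    ----------
    input_signal
        A single ``SampledSignal``, a list of them (one per stimulus,
        pooled by concatenation), or a list of such lists (one per
        replicate).
    outputs
        dict mapping output label -> structure matching ``input_signal``
        (same nesting: signal / list per stimulus / list of lists).
    feature_specs
        The feature recipes to evaluate against every output.
    window
        Optional analysis window (s) applied around each stimulus epoch.
    """
    def _as_replicates(obj):
        if isinstance(obj, SampledSignal):
            return [[obj]]
        if obj and isinstance(obj[0], SampledSignal):
            return [list(obj)]
        return [list(rep) for rep in obj]

    in_reps = _as_replicates(input_signal)
    results = []
    for spec in feature_specs:
        feat_reps = [[compute_feature(s, spec) for s in rep] for rep in in_reps]
        for label, out in outputs.items():
            out_reps = _as_replicates(out)
            if len(out_reps) != len(in_reps):
                raise ValueError("replicate structure of outputs must match inputs")
            rhos = []
            n_total = 0
            for feats, outs in zip(feat_reps, out_reps):
                xs, ys = [], []
                for f, o in zip(feats, outs):
                    xv, yv = aligned_samples(f, o, window)
                    xs.append(xv)
                    ys.append(yv)
                xcat = np.concatenate(xs)
                ycat = np.concatenate(ys)
                n_total += xcat.size
                rhos.append(cross_correlation_coefficient(xcat, ycat))
            results.append(
                CorrelationResult(
                    input_feature=spec.feature,
                    output_label=label,
                    rho=float(np.mean(rhos)),
                    n_samples=n_total,
                    per_fly_rhos=rhos,
                )
            )
    return results


def compare_correlations(
    result_a: CorrelationResult,
    result_b: CorrelationResult,
) -> dict:
    """Two-sided two-sample t-test between per-replicate rho distributions."""
    a = np.asarray(result_a.per_fly_rhos, dtype=float)
    b = np.asarray(result_b.per_fly_rhos, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    t_stat, p = stats.ttest_ind(a, b)
    return {
        "feature_a": result_a.input_feature,
        "feature_b": result_b.input_feature,
        "output": result_a.output_label,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t_stat": float(t_stat),
        "p_value": float(p),
    }
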