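"""2D linear-nonlinear model of the OSN-to-PN transformation.

The PN spike rate z is modelled as a static function of the OSN spike
rate y and its rate of change: z = f(y, dy/dt).  The nonlinearity f is
estimated on a rectangular grid (100 x 100 nodes by default) from
(y, dy/dt, z) triples sampled every 25 ms: each sample contributes to
its four enclosing nodes through bilinear weights, and the node values v
minimize

    || z - A v ||^2  +  lambda * R(v)

where A holds the bilinear weights and R blends magnitude shrinkage
with smoothing: R = alpha ||v||^2 + (1 - alpha) (||L v||^2 + 0.1 ||G v||^2),
L the discrete 5-point Laplacian and G the first-difference (gradient)
operator on the grid.  At the default alpha = 0 the penalty is pure
smoothing: the curvature term interpolates the surface across the
unsampled interior between stimulus trajectories and the gradient term
extends it as a constant beyond the data envelope, so unvisited cells
neither collapse to zero nor grow without bound.  By default lambda is
chosen by blocked cross-validation (contiguous time blocks held out
within each stimulus), which respects the temporal correlation of the
samples; generalized cross-validation is available as an option.
Prediction reads the surface by bilinear interpolation with boundary
clamping and floors the output at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .signal_processing import FeatureSpec, compute_feature
from .signals import SampledSignal

__all__ = [
    "RegressionSampleSet",
    "Nonlinearity2D",
    "PredictionReport",
    "build_samples",
    "fit_nonlinearity",
    "predict",
    "rmse",
    "conditional_gain",
]


@dataclass
class RegressionSampleSet:
    """(y, dy/dt, z) triples pooled across stimuli at a fixed interval."""

    y: np.ndarray
    dydt: np.ndarray
    z: np.ndarray
    sampling_interval: float = 0.025
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.dydt = np.asarray(self.dydt, float)
        self.z = np.asarray(self.z, float)
        if not (self.y.size == self.dydt.size == self.z.size):
            raise ValueError("y, dydt, z must have equal length")
        for arr in (self.y, self.dydt, self.z):
            if not np.all(np.isfinite(arr)):
                raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return self.y.size

    def extend(self, other: "RegressionSampleSet") -> "RegressionSampleSet":
        return RegressionSampleSet(
            y=np.concatenate([self.y, other.y]),
            dydt=np.concatenate([self.dydt, other.dydt]),
            z=np.concatenate([self.z, other.z]),
            sampling_interval=self.sampling_interval,
            provenance=self.provenance + other.provenance,
        )


@dataclass
class Nonlinearity2D:
    """f(y, dy/dt) as values on a rectangular grid."""

    y_axis: np.ndarray
    dydt_axis: np.ndarray
    values: np.ndarray                  # shape (len(y_axis), len(dydt_axis))
    ridge_lambda: float = 0.0
    smoothness_alpha: float = 0.0
    node_support: np.ndarray | None = None  # bilinear weight mass per node

    def __post_init__(self) -> None:
        self.y_axis = np.asarray(self.y_axis, float)
        self.dydt_axis = np.asarray(self.dydt_axis, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.y_axis) <= 0) or np.any(np.diff(self.dydt_axis) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if self.values.shape != (self.y_axis.size, self.dydt_axis.size):
            raise ValueError("values shape must match the axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    # -- serialisation (self-describing JSON container) ------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "y_axis": self.y_axis.tolist(),
            "dydt_axis": self.dydt_axis.tolist(),
            "values": self.values.tolist(),
            "ridge_lambda": self.ridge_lambda,
            "smoothness_alpha": self.smoothness_alpha,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "Nonlinearity2D":
        d = json.loads(Path(path).read_text())
        return cls(
            y_axis=np.asarray(d["y_axis"]),
            dydt_axis=np.asarray(d["dydt_axis"]),
            values=np.asarray(d["values"]),
            ridge_lambda=d["ridge_lambda"],
            smoothness_alpha=d["smoothness_alpha"],
        )


@dataclass
class PredictionReport:
    stimulus_label: str
    predicted: SampledSignal
    observed: SampledSignal
    rmse: float


# ---------------------------------------------------------------------------
# sample construction
# ---------------------------------------------------------------------------

def build_samples(
    osn_rate: SampledSignal,
    pn_rate: SampledSignal,
    feature: FeatureSpec | None = None,
    sampling_interval: float = 0.025,
    label: str = "",
) -> RegressionSampleSet:
    """(y, dy/dt, z) triples at a fixed interval over the common support.

    dy/dt is derived from the OSN rate with the OSN feature defaults
    (4 Hz low-pass, 100-ms forward difference); y, dy/dt and z are read
    at shared timestamps every ``sampling_interval`` by interpolation.
    """
    feature = feature or FeatureSpec.for_kind("osn", "rate_of_change")
    if feature.signal_kind != "osn":
        raise ValueError("feature.signal_kind must be 'osn'")
    deriv = compute_feature(osn_rate, FeatureSpec(
        "rate_of_change", "osn", feature.delta_roc, feature.delta_acc,
        feature.cutoff_amp, feature.cutoff_roc,
    ))
    t_lo = max(osn_rate.t0, deriv.t0, pn_rate.t0)
    t_hi = min(osn_rate.t_end, deriv.t_end, pn_rate.t_end)
    if t_hi <= t_lo:
        raise ValueError("OSN and PN signals have non-overlapping supports")
    n = int(np.floor((t_hi - t_lo) / sampling_interval + 1e-9)) + 1
    grid = t_lo + sampling_interval * np.arange(n)
    return RegressionSampleSet(
        y=osn_rate.value_at(grid),
        dydt=deriv.value_at(grid),
        z=pn_rate.value_at(grid),
        sampling_interval=sampling_interval,
        provenance=[label] * n,
    )


# ---------------------------------------------------------------------------
# ridge fit
# ---------------------------------------------------------------------------

def _bilinear_design(
    y: np.ndarray,
    d: np.ndarray,
    y_axis: np.ndarray,
    d_axis: np.ndarray,
) -> sparse.csr_matrix:
    """Sparse design matrix: each sample -> bilinear weights on 4 nodes."""
    ny, nd = y_axis.size, d_axis.size
    iy = np.clip(np.searchsorted(y_axis, y, side="right") - 1, 0, ny - 2)
    idd = np.clip(np.searchsorted(d_axis, d, side="right") - 1, 0, nd - 2)
    fy = (y - y_axis[iy]) / (y_axis[iy + 1] - y_axis[iy])
    fd = (d - d_axis[idd]) / (d_axis[idd + 1] - d_axis[idd])
    fy = np.clip(fy, 0.0, 1.0)
    fd = np.clip(fd, 0.0, 1.0)
    rows = np.repeat(np.arange(y.size), 4)
    cols = np.concatenate([
        iy * nd + idd,
        iy * nd + idd + 1,
        (iy + 1) * nd + idd,
        (iy + 1) * nd + idd + 1,
    ]).reshape(4, -1).T.ravel()
    w = np.concatenate([
        (1 - fy) * (1 - fd),
        (1 - fy) * fd,
        fy * (1 - fd),
        fy * fd,
    ]).reshape(4, -1).T.ravel()
    return sparse.csr_matrix((w, (rows, cols)), shape=(y.size, ny * nd))


def _laplacian(ny: int, nd: int) -> sparse.csr_matrix:
    """5-point discrete Laplacian; boundary rows use no penalty (zero rows)."""
    def second_diff(n):
        main = np.zeros(n)
        main[1:-1] = -2.0
        off = np.zeros(n - 1)
        off[:] = 1.0
        off_l = off.copy()
        off_l[-1] = 0.0  # last interior row only
        off_u = off.copy()
        off_u[0] = 0.0
        return sparse.diags([off_u, main, off_l], [-1, 0, 1])

    eye_y = sparse.identity(ny)
    eye_d = sparse.identity(nd)
    return (sparse.kron(second_diff(ny), eye_d) + sparse.kron(eye_y, second_diff(nd))).tocsr()


def _gradient_gram(ny: int, nd: int) -> sparse.csr_matrix:
    """G^T G for the stacked first-difference operators on both axes.

    Penalizing the surface gradient extends the fit as a *constant* into
    regions without data support, instead of shrinking them to zero
    (magnitude penalty) or letting them grow linearly without bound
    (curvature penalty alone).
    """
    def d1(n):
        return sparse.diags([np.full(n - 1, -1.0), np.ones(n - 1)], [0, 1],
                            shape=(n - 1, n))

    gy = sparse.kron(d1(ny), sparse.identity(nd))
    gd = sparse.kron(sparse.identity(ny), d1(nd))
    return (gy.T @ gy + gd.T @ gd).tocsr()


def _grid_axes(samples: RegressionSampleSet, grid_shape: tuple,
               margin: float = 0.05) -> tuple:
    """Data-driven extents with a relative margin on each side."""
    def axis(vals, n):
        lo, hi = float(vals.min()), float(vals.max())
        span = hi - lo
        if span <= 0:
            raise ValueError("degenerate (zero-extent) sample range on an axis")
        return np.linspace(lo - margin * span, hi + margin * span, n)

    return axis(samples.y, grid_shape[0]), axis(samples.dydt, grid_shape[1])


#: weight of the gradient term relative to curvature inside the smoothing
#: penalty; keeps far-from-data regions flat rather than linearly growing
_GRADIENT_WEIGHT = 0.1


def fit_nonlinearity(
    samples: RegressionSampleSet,
    grid_shape: tuple = (100, 100),
    ridge_lambda: float | str = "cv",
    smoothness_alpha: float = 0.0,
    margin: float = 0.05,
) -> Nonlinearity2D:
    """Estimate f(y, dy/dt) on a grid by penalized least squares.

    ``ridge_lambda`` may be a nonnegative float, ``"cv"`` (default) or
    ``"gcv"``.  ``"cv"`` picks the penalty weight by leave-one-stimulus-
    out cross-validation over the sample provenance groups — appropriate
    because samples along one stimulus trajectory are temporally
    correlated, which makes GCV (which assumes independent errors)
    undersmooth.  ``"gcv"`` minimizes the generalized cross-validation
    score (Hutchinson trace estimate with fixed probes, deterministic)
    and is also the fallback when the samples carry fewer than two
    provenance groups.

    ``smoothness_alpha`` blends magnitude shrinkage (alpha = 1,
    classical ridge) with smoothing (alpha = 0, the default: curvature
    plus a weak gradient term).  Smoothing is preferred as the default
    because the regression samples lie on one-dimensional trajectories
    in the (y, dy/dt) plane: magnitude shrinkage collapses the
    unsampled interior between trajectories toward zero, whereas the
    smoothing penalty interpolates across it and extends the surface as
    a constant beyond the data envelope.
    """
    if samples.n < 1:
        raise ValueError("need at least one sample")
    if not 0.0 <= smoothness_alpha <= 1.0:
        raise ValueError("smoothness_alpha must be in [0, 1]")
    y_axis, d_axis = _grid_axes(samples, grid_shape, margin)
    A = _bilinear_design(samples.y, samples.dydt, y_axis, d_axis)
    z = samples.z
    n_nodes = y_axis.size * d_axis.size
    AtA = (A.T @ A).tocsc()
    Atz = A.T @ z
    L = _laplacian(y_axis.size, d_axis.size)
    # alpha blends magnitude shrinkage against smoothing; the smoothing part
    # is curvature plus a weaker gradient term (see _gradient_gram)
    P = (smoothness_alpha * sparse.identity(n_nodes)
         + (1.0 - smoothness_alpha)
         * (L.T @ L + _GRADIENT_WEIGHT * _gradient_gram(y_axis.size, d_axis.size))
         ).tocsc()
    # relative scale so lambda ~ 1 balances the data and penalty terms
    scale = (AtA.diagonal().mean() / max(P.diagonal().mean(), 1e-300))
    jitter = 1e-10 * scale * sparse.identity(n_nodes, format="csc")

    def solve(ata, lam_eff):
        # tiny absolute jitter keeps nodes with zero data support solvable
        return splu((ata + lam_eff * P + jitter).tocsc())

    groups = sorted(set(samples.provenance)) if samples.provenance else []
    if ridge_lambda == "cv" and len(groups) < 2:
        ridge_lambda = "gcv"

    if ridge_lambda == "cv":
        # blocked K-fold: contiguous ~0.5-s blocks within each stimulus,
        # assigned round-robin to folds.  Blocks are longer than the
        # feature filters' correlation time, so held-out blocks are
        # effectively independent, while every fold keeps support across
        # the whole trajectory envelope (matching the prediction task,
        # which interpolates inside the envelope rather than
        # extrapolating to an unseen trajectory).
        candidates = np.logspace(0, 4, 7)
        k_folds, block = 5, 20
        prov = np.asarray(samples.provenance)
        fold_id = np.zeros(samples.n, dtype=int)
        for g in groups:
            idx = np.where(prov == g)[0]
            fold_id[idx] = (np.arange(idx.size) // block) % k_folds
        folds = []
        for k in range(k_folds):
            mask = fold_id == k
            A_in, A_out = A[~mask], A[mask]
            folds.append((
                (A_in.T @ A_in).tocsc(), A_in.T @ z[~mask], A_out, z[mask]
            ))
        best = (np.inf, candidates[0])
        for lam in candidates:
            sse = 0.0
            for ata_in, atz_in, A_out, z_out in folds:
                v = solve(ata_in, lam * scale).solve(atz_in)
                r = z_out - A_out @ v
                sse += float(r @ r)
            if sse < best[0]:
                best = (sse, lam)
        lam = best[1]
    elif ridge_lambda == "gcv":
        candidates = np.logspace(-6, 2, 9)
        rng = np.random.default_rng(0)  # fixed probes: deterministic fit
        probes = rng.choice([-1.0, 1.0], size=(4, samples.n))
        best = (np.inf, candidates[0])
        for lam in candidates:
            lu = solve(AtA, lam * scale)
            v = lu.solve(Atz)
            resid = z - A @ v
            # Hutchinson estimate of tr(S), S = A M^-1 A^T
            tr = float(np.mean([
                u @ (A @ lu.solve(A.T @ u)) for u in probes
            ]))
            tr = min(tr, samples.n * (1 - 1e-9))
            gcv = (resid @ resid / samples.n) / (1 - tr / samples.n) ** 2
            if gcv < best[0]:
                best = (gcv, lam)
        lam = best[1]
    else:
        lam = float(ridge_lambda)
        if lam < 0:
            raise ValueError("ridge_lambda must be nonnegative")
    if lam > 0:
        v = solve(AtA, lam * scale).solve(Atz)
    else:
        # lambda = 0: plain least squares (requires full data support)
        M = (AtA + 1e-12 * sparse.identity(n_nodes, format="csc")).tocsc()
        v = splu(M).solve(Atz)
    support = np.asarray(np.abs(A).sum(axis=0)).ravel()
    return Nonlinearity2D(
        y_axis=y_axis,
        dydt_axis=d_axis,
        values=v.reshape(y_axis.size, d_axis.size),
        ridge_lambda=float(lam),
        smoothness_alpha=smoothness_alpha,
        node_support=support.reshape(y_axis.size, d_axis.size),
    )


# ---------------------------------------------------------------------------
# prediction and scoring
# ---------------------------------------------------------------------------

def evaluate_surface(model: Nonlinearity2D, y, dydt) -> np.ndarray:
    """Bilinear interpolation with boundary clamping (no output floor)."""
    y = np.clip(np.asarray(y, float), model.y_axis[0], model.y_axis[-1])
    d = np.clip(np.asarray(dydt, float), model.dydt_axis[0], model.dydt_axis[-1])
    ny, nd = model.y_axis.size, model.dydt_axis.size
    iy = np.clip(np.searchsorted(model.y_axis, y, side="right") - 1, 0, ny - 2)
    idd = np.clip(np.searchsorted(model.dydt_axis, d, side="right") - 1, 0, nd - 2)
    fy = (y - model.y_axis[iy]) / (model.y_axis[iy + 1] - model.y_axis[iy])
    fd = (d - model.dydt_axis[idd]) / (model.dydt_axis[idd + 1] - model.dydt_axis[idd])
    V = model.values
    return (
        V[iy, idd] * (1 - fy) * (1 - fd)
        + V[iy, idd + 1] * (1 - fy) * fd
        + V[iy + 1, idd] * fy * (1 - fd)
        + V[iy + 1, idd + 1] * fy * fd
    )


def predict(
    osn_rate: SampledSignal,
    model: Nonlinearity2D,
    feature: FeatureSpec | None = None,
) -> SampledSignal:
    """Forward-run the fitted model on a new OSN rate trace.

    z(t) is the surface read-out at (y(t), dy/dt(t)); queries outside
    the grid are clamped to the boundary, and the output is floored at
    zero (firing rates are nonnegative).
    """
    feature = feature or FeatureSpec.for_kind("osn", "rate_of_change")
    deriv = compute_feature(osn_rate, FeatureSpec(
        "rate_of_change", "osn", feature.delta_roc, feature.delta_acc,
        feature.cutoff_amp, feature.cutoff_roc,
    ))
    y = osn_rate.values[: deriv.n]
    z = evaluate_surface(model, y, deriv.values)
    return SampledSignal(
        t0=osn_rate.t0,
        sample_period=osn_rate.sample_period,
        values=np.maximum(z, 0.0),
        units="spike/s",
    )


def rmse(
    predicted: SampledSignal,
    observed: SampledSignal,
    window: tuple | None = None,
) -> float:
    """Root-mean-square difference over shared timestamps in ``window``."""
    t_lo = max(predicted.t0, observed.t0)
    t_hi = min(predicted.t_end, observed.t_end)
    if window is not None:
        t_lo = max(t_lo, window[0])
        t_hi = min(t_hi, window[1])
    if t_hi <= t_lo:
        raise ValueError("empty overlap between predicted and observed")
    coarse = predicted if predicted.sample_period >= observed.sample_period else observed
    grid = coarse.window(t_lo, t_hi).times
    diff = predicted.value_at(grid) - observed.value_at(grid)
    return float(np.sqrt(np.mean(diff ** 2)))


def conditional_gain(model: Nonlinearity2D, fixed_y: float) -> float:
    """Slope beta of the surface vs dy/dt on the positive half at fixed y.

    Least-squares slope of f(fixed_y, d) against d over grid nodes with
    d > 0, in (spike/s) per (spike/s^2) — i.e. seconds.
    """
    if not model.y_axis[0] <= fixed_y <= model.y_axis[-1]:
        raise ValueError("fixed_y outside the fitted grid")
    pos = model.dydt_axis > 0
    if pos.sum() < 2:
        raise ValueError("grid has fewer than 2 positive-dy/dt nodes")
    d = model.dydt_axis[pos]
    vals = evaluate_surface(model, np.full(d.size, fixed_y), d)
    d_c = d - d.mean()
    return float((d_c @ (vals - vals.mean())) / (d_c @ d_c))
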