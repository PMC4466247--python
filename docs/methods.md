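# Methods

## The model

The pipeline studies the two-stage transformation of a time-varying
odor concentration x(t) into olfactory sensory neuron (OSN) and
projection neuron (PN) spike rates:

1. **Odor → OSN.**  A minimal phenomenological encoder

       y(t) = clip(r₀ + g_a · x(t) + g_r · ⌈dx/dt⌉₊ , 0, r_max)

   with spontaneous rate r₀ (default 5 spike/s), amplitude gain g_a
   ((spike/s)/ppm, default 0.5), rate-of-change gain g_r
   ((spike/s)/(ppm/s), default 3.0), saturation r_max (300 spike/s) and
   a forward-difference derivative at interval 50 ms.  ⌈·⌉₊ denotes
   half-wave rectification.  This is *not* a biophysical transduction
   model (no receptor kinetics, no adaptation): it is the simplest
   encoder that reproduces the qualitative response repertoire the
   analysis depends on — a step-shaped rate for a ramp odor, a
   ramp-shaped rate for a parabola odor, and concentration sensitivity.

2. **OSN → PN.**  A static two-dimensional nonlinearity

       z(t) = f(y(t), dy/dt(t))

   — the classical linear–nonlinear structure with amplitude and
   rate-of-change input channels.  The synthetic ground truth is

       f*(y, d) = clip(c₀ + c_y·y + β₀·exp(−γ·y)·⌈d⌉₊ , 0, z_max)

   with c₀ = 5 spike/s, c_y = 0.25, β₀ = 1.1 s, γ = 0.008 (spike/s)⁻¹,
   z_max = 300 spike/s.  Its conditional gain β(y) = β₀·e^(−γy) is the
   slope of the PN rate against the OSN rate of change at fixed
   amplitude; it decays with amplitude (β(30) ≈ 0.87, β(120) ≈ 0.42),
   giving the PN its onset-emphasising, amplitude-compressing character.
   Gains were set so OSN rates span 0–150 spike/s and PN peaks reach
   ~250–300 spike/s, matching the dynamic ranges these neuron classes
   exhibit.

Trial-to-trial variability is modelled as an inhomogeneous Poisson
process (thinning against the peak rate; expected count = ∫rate dt).
Real spike trains of driven sensory neurons are often sub-Poisson, so
this is a conservative (noisier) choice; trial counts default to 5 per
neuron and stimulus.

## Rate and feature estimation

- **PSTH**: 100-ms bins advancing by 25 ms (75-ms overlap); bin value
  = total spike count across trials / (n_trials × bin width), in
  spike/s, timestamped at the bin *centre*.  Bins are half-open
  [start, start + width), and every bin intersecting the recording
  window is evaluated, so each interior spike is counted exactly
  width/step = 4 times across bins.  Centre timestamps minimise
  systematic lag against the stimulus; all later joins are on
  timestamps, never array indices.
- **Derivatives**: the forward difference dx/dt = [x(t+Δ) − x(t)]/Δ,
  aligned to t, with Δ an integer multiple of the sample period.
  Δ = 50 ms for the odor rate of change; Δ = 100 ms for odor
  acceleration and both OSN derivative stages.  Trailing samples with
  no lookahead are dropped by default (zero-padding is available).
- **Low-pass filtering** precedes each differencing stage, because the
  difference operator amplifies high frequencies: 20 Hz for the odor
  amplitude, 10 Hz for the odor rate of change, 4 Hz for the OSN rate
  and OSN rate of change.  The filter is a 2nd-order Butterworth
  applied forward and backward (zero phase — phase distortion would
  corrupt every peak-time result).  The two-pass magnitude response is
  the square of the one-pass response, so the design frequency is
  pre-warped by (√2 − 1)^(1/4) ≈ 0.80 to put the overall −3 dB point at
  the nominal cutoff.

The quarter-cycle property of differentiation — the derivative of
sin(ωt) leads it by π/2 — holds for the discrete operator up to a bias
of ωΔ/2 (0.2% of π/2 at 1 Hz, 1-ms sampling), which the validation
suite measures.

## Designing the triangle ensemble

To probe the (y, dy/dt) input plane efficiently, the OSN stage is
driven so that its output rates are triangles: each up/down ramp
sweeps a range of amplitudes at one positive and one negative slope.
For a pure rate-of-change encoder (g_a = 0) the required odor is
obtained analytically: concentration must be the running integral of
(target − r₀)/g_r, a monotone piecewise-quadratic "S-parabola" whose
time derivative is the target triangle.  The discontinuous return to
baseline after the stimulus is invisible to the encoder (negative
derivative, rectified away), so the round trip is exact on both the
rising and falling phases up to the O(Δ) discretisation of the forward
difference (residual ≤ slope·Δ, reported in the tests).  With g_a ≠ 0
the inverse is a linear ODE with no closed waveform representation;
the design function rejects that case.

The default battery holds five triangles with peak times 0.6–1.7 s
after onset and peak rates 90–150 spike/s, paired so rising slopes
spread over ~50–240 spike/s².  The held-out cross-validation input is
a step pulse (0.5-s linear rise to 120 spike/s, 0.8-s hold, 0.5-s
fall) whose rise slope lies inside the training ensemble's slope
envelope — cross-validation is meant to test generalisation *on* the
fitted surface, not extrapolation beyond the sampled region.

## Estimating the 2D nonlinearity

(y, dy/dt, z) triples are read every 25 ms from the OSN rate estimate,
its derivative feature, and the PN rate estimate, pooled across
stimuli.  The surface is parameterised by its values v on a 100 × 100
grid whose extents cover the samples with a 5% margin; each sample
loads its four enclosing nodes with bilinear weights (design matrix A).
The fit minimises

    ‖z − A v‖² + λ [ α‖v‖² + (1 − α)(‖L v‖² + 0.1‖G v‖²) ]

with L the 5-point discrete Laplacian and G the first-difference
(gradient) operator.  The default is α = 0, i.e. pure smoothing.  The
reason is geometric: the samples lie on one-dimensional trajectories
(loops) in the input plane, so most grid nodes carry no data.  A
magnitude penalty pulls such nodes to zero within a couple of grid
spacings, carving spurious valleys between trajectories; a curvature
penalty alone extends the surface *linearly* into unsupported corners,
where boundary-clamped queries then read arbitrarily large values.
The added gradient term (weight 0.1 relative to curvature) makes the
unsupported far field tend to a constant — the only extension that is
both bounded and unbiased toward zero.  α = 1 recovers classical ridge
shrinkage; the training residual is nondecreasing in λ for any fixed α.

λ is selected by blocked cross-validation: contiguous ~0.5-s blocks of
samples within each stimulus are assigned round-robin to 5 folds, and
the candidate grid 10⁰…10⁴ (relative to a scale that balances the data
and penalty Grams) is scored by held-out squared error.  Blocks are
longer than the feature filters' correlation time, so held-out blocks
are effectively independent, while every fold retains support across
the whole trajectory envelope — matching the prediction task, which
interpolates inside the envelope.  Generalized cross-validation (with
a deterministic Hutchinson trace estimate) is available as an option
and is the automatic fallback when the samples carry fewer than two
stimulus labels; it assumes independent errors and undersmooths on
temporally correlated samples, which is why it is not the default.
A 10⁻¹⁰-scale diagonal jitter keeps the normal equations solvable when
λ = 0 leaves unsupported nodes unconstrained.

Prediction reads the surface by bilinear interpolation; queries outside
the grid are clamped to the nearest boundary node (so predictions can
never leave the fitted value range), and the output is floored at zero
because firing rates are nonnegative — the regression itself is
unconstrained.  A known weakness of this model class is preserved
deliberately: the steep low-amplitude gain makes it overestimate the
PN rate before and after the stimulus; no ad-hoc baseline suppression
is applied, and the effect is visible in the prediction reports.

The conditional gain β(y) is extracted from a fitted surface as the
least-squares slope of f(y, ·) over the positive-derivative grid nodes.

## Correlation analysis

The zero-lag normalized cross-covariance

    ϱ(x, y) = (1/N) Σᵢ (x[i] − μₓ)(y[i] − μᵧ) / (σₓ σᵧ)

(population standard deviations) is evaluated after resampling both
signals onto the coarser signal's timestamps over the intersection of
their supports, restricted to an analysis window from 0.5 s before
stimulus onset to 1.0 s after offset.  Per replicate ("fly") the
samples of the whole stimulus battery are concatenated before
correlating; summaries report the mean ± sd of ϱ across replicates,
and feature rows are compared with a two-sided two-sample t-test.
Although the name "cross-correlation" suggests a lag scan, only the
zero-lag coefficient enters the analysis; a lag scan is not part of
the default outputs.

The default replicate structure mirrors a 9-fly experiment: five
replicates at full stimulus amplitude and four at half amplitude, each
with independent Poisson noise.

## Peak-time analysis

Peak times are the timestamps of the maximum sample within a window
from 0.2 s before onset to 0.3 s after offset, ties broken by the
earliest time (relevant when the PN transient saturates).  The odor
peak-time design grid (0.600–1.700 s after onset in seven ~157-ms
steps) is rounded to the 1-ms sample grid so the generated peak is
exact.  For any single-peaked input, rectified differentiation can
only advance the peak, so the cascade ordering
t_peak(rectified 2nd derivative) ≤ t_peak(rectified 1st derivative) ≤
t_peak(input) holds, strictly for triangles with positive rise time.

## Problem sizes and determinism

Default runs use 1-ms odor sampling (figures 2 and 4), 5-ms sampling
for the designed rate traces (figure 3), 4-s records, 5 Poisson trials
per neuron, 9 correlation replicates and 100 × 100 fitting grids; a
full three-figure run completes in well under a minute on one CPU.
Every random stage draws its seed deterministically from the master
seed via a CRC-keyed seed sequence, so a fixed seed reproduces every
output file byte-for-byte.

## What the synthetic world does and does not show

The generator reproduces the *structure* the analysis assumes:
rate-of-change encoding at both stages, rectification, gain that falls
with amplitude, realistic rate ranges and trial counts, Poisson trial
noise.  It omits receptor adaptation and dynamics (the OSN peak
advancement it produces is the ~Δ of the difference operator, much
smaller than in real recordings), sub-Poisson spiking statistics,
odorant- and glomerulus-specific differences, and measurement noise on
the concentration signal.  Passing tests therefore demonstrate that
the estimation machinery recovers a known system of the hypothesised
form under realistic sampling and noise — not that the form itself is
the correct physiology.

Under the default noise conditions, the held-out prediction error is
dominated by the propagation of spike-count noise through the
derivative feature: with 5 Poisson trials, the 4-Hz/100-ms feature
chain leaves a rate-of-change noise scale of order 10² spike/s², which
the steep low-amplitude gain converts into onset-transient prediction
error.  Predicting with the *ground-truth* surface from the same noisy
features gives errors of the same size as the fitted model's (the
validation suite computes both), i.e. the fit operates at the noise
floor of the features rather than at a deficiency of the estimator.
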