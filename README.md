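# odorln

Temporal odor-signal processing in the *Drosophila* odor → OSN → PN
pathway, as a tested, reusable analysis pipeline.

Flying insects meet odors as short, turbulent plumes, and the early
olfactory circuit does not relay the raw concentration signal.
First-order olfactory sensory neurons (OSNs) respond to the odor
concentration *and* its rate of change; second-order projection neurons
(PNs) in the antennal lobe are in turn driven strongly by the rate of
change of the OSN rate — so, relative to the stimulus, PN output
emphasises the second derivative (acceleration) of concentration.  A
cascade of differentiating stages shifts response peaks toward the
stimulus onset, letting downstream circuits react to a slowly rising
plume long before its concentration peaks.

`odorln` implements the full analysis around that idea for synthetic
data with known ground truth:

- **Stimulus and response synthesis** — polynomial odor waveforms
  (pulse, ramp, parabola, triangle), a phenomenological OSN encoder
  `r(t) = clip(r₀ + g_a·x(t) + g_r·⌈dx/dt⌉₊)`, a ground-truth PN
  nonlinearity with rectified rate-of-change drive and
  amplitude-dependent gain, and inhomogeneous-Poisson spike trains.
- **Rate and feature estimation** — PSTHs with 100-ms bins advancing by
  25 ms; amplitude / rate-of-change / acceleration signals via
  zero-phase low-pass filtering and forward differences
  `dx/dt = [x(t+Δ) − x(t)]/Δ`.
- **Feature-correlation analysis** — the zero-lag normalized
  cross-covariance ϱ(x, y) = (1/N)Σᵢ(x[i]−μₓ)(y[i]−μᵧ)/(σₓσᵧ) between
  each input feature and each output, pooled per replicate, with
  two-sample t-tests between feature rows.
- **2D linear–nonlinear model estimation** — the PN rate modelled as
  z = f(y, dy/dt) of the OSN rate; f estimated on a 100 × 100 grid by
  penalized (ridge-type) least squares from (y, dy/dt, z) triples
  sampled every 25 ms, with forward prediction, RMSE scoring, and
  conditional-gain slices β(y) = ∂f/∂(dy/dt).
- **Peak-time analysis** — stagewise advancement
  t_peak(PN) < t_peak(OSN) < t_peak(odor) across a triangle battery
  with peak times spread over 0.6–1.7 s after onset.

## Worked example

Each figure-level analysis is a library call (`odorln.run_figure2_analysis`,
`run_figure3_pipeline`, `run_figure4_analysis`) and a CLI subcommand.

Fit the 2D nonlinearity from five triangle-shaped OSN inputs (induced by
a designed parabola odor ensemble, with 5 Poisson trials per neuron) and
predict six stimuli, one of them a held-out step pulse:

```text
$ odorln fig3 --seed 1
  triangle_1: RMSE = 29.4 spike/s
  triangle_2: RMSE = 24.8 spike/s
  triangle_3: RMSE = 13.5 spike/s
  triangle_4: RMSE = 12.7 spike/s
  triangle_5: RMSE = 20.7 spike/s
  step_pulse: RMSE = 37.3 spike/s (held out)
average RMSE = 23.1 spike/s
```

The per-stimulus numbers are root-mean-square differences between the
predicted and observed PN rate (peak PN rates here are ~250–300
spike/s); the held-out step pulse was never used in the fit, so its
error measures genuine generalisation.

Peak-time advancement across eight triangle odor waveforms:

```text
$ odorln fig4 --seed 1
  triangle_1: odor 1.100 s, OSN 1.050 s, PN 0.349 s
  ...
  triangle_8: odor 2.200 s, OSN 2.150 s, PN 0.409 s
stagewise advancement: ok
```

While the odor peaks sweep 1.10–2.20 s, the PN peaks stay pinned near
the stimulus onset (0.35–0.41 s): the PN response is a stereotyped
onset detector, as the cascade-of-derivatives picture predicts.

Feature-correlation structure (9 synthetic replicates — five at full
and four at half concentration):

```text
$ odorln fig2 --seed 1
      amplitude -> osn: rho = 0.293 +/- 0.061
 rate_of_change -> osn: rho = 0.361 +/- 0.049
   acceleration -> pn: rho = 0.166 +/- 0.019
  ...
PN acc vs amp: t = 39.89, p = 1.91e-17
```

The OSN rate correlates best with the concentration and its rate of
change, while the PN rate correlates best with the acceleration — the
acceleration-vs-amplitude contrast for PNs is significant far below
p = 0.001.

All subcommands take `--config run.yaml` (stimulus battery, encoder
gains, trial counts, fit hyperparameters), `--seed`, `--outdir`,
`--lambda` and `--alpha`; outputs are delimited-text traces and tables,
a JSON model container, and a manifest sufficient to re-execute the
run.  A fixed seed makes every output byte-identical across runs.

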