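# smtkit

Single-molecule tracking (SMT) analysis for transcription-factor dynamics in
the nucleus: who is chromatin-bound, who is confined, who diffuses freely,
and for how long molecules stay bound.

Live-cell SMT of HaloTag-labelled factors (e.g. the glucocorticoid receptor)
produces thousands of short 2D trajectories under two acquisition regimes — a
continuous ~83 Hz channel that resolves diffusion, and a 5 Hz time-lapse
channel that isolates bound molecules and their residence times. `smtkit`
implements the full analysis chain for such data, plus a ground-truth
trajectory simulator that makes every stage testable without a microscope:

* **simulate** — multi-state Brownian motion (free / confined-in-a-disk /
  bound) with state switching, camera motion blur, localization noise and
  photobleaching; optional rendering to TIFF image stacks.
* **track** — spot detection (matched filter + sub-pixel Gaussian fit) and
  optimal-assignment frame-to-frame linking with the standard pixel limits
  (4 px at 5 Hz, 6 px at 83 Hz), no gap closing, minimum two frames.
* **states** — classification of whole trajectories into K diffusive states
  by perturbation expectation-maximization (pEM) with BIC selection of K,
  posterior-weighted MSD curves, a ≥5%-population / 0.6-posterior state
  filter, and bound / confined / free fraction summaries.
* **residence** — dwell-time extraction from the slow channel, cell-weighted
  pooling, photobleaching correction by dividing out a triple-exponential
  survival fitted to a permanently bound control (histone H2B), power-law
  tail fitting by maximum likelihood, and two-sample KS comparison of
  conditions.

## The model in brief

Under state *k*, a track's per-axis displacement sequence is a zero-mean
Gaussian with tridiagonal covariance

```
Var(Δ) = 2 D_k Δt + 2 ε_k²,   Cov(Δ_i, Δ_{i+1}) = −ε_k²,   ε_k² = σ² − D_k t_E/3
```

where Δt is the frame interval, t_E the exposure, σ the static localization
precision, and ε² the *effective* noise after motion blur (state-dependent;
negative when blur exceeds noise). pEM maximizes the K-state mixture
likelihood over whole tracks, with log-normal parameter perturbations to
escape local optima, and BIC = −2 lnL + p ln(n_displacements) picks K.

Corrected residence survival is `S_corr(t) = S_obs(t) / S_b(t)` with
`S_b(t) = Σ A_i exp(−t/τ_i)` the fluorophore (H2B-control) survival, and the
bound-time tail follows a power law whose exponent is estimated as
`α = 1 + n / Σ ln(t_i/t_min)`.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate the canonical two-state experiment (2,000 tracks at the fast
protocol; a bound-like state D = 0.02 µm²/s with weight 0.3 and a free state
D = 0.5 µm²/s with weight 0.7, σ = 30 nm), then recover the mixture:

```python
import numpy as np
from smtkit import (AcquisitionProtocol, MotionState, SimulationModel,
                    simulate_switching_tracks, select_model, filter_states,
                    summarize_fractions)

proto = AcquisitionProtocol(0.012, 0.010, n_frames=21, label="fast")
model = SimulationModel(
    states=(MotionState("bound", 0.02), MotionState("free", 0.5)),
    initial_weights=(0.3, 0.7), localization_sigma_um=0.03, seed=1)
tracks, truth = simulate_switching_tracks(model, proto, n_tracks=2000)

sel = filter_states(select_model(tracks, range(1, 5), seed=1,
                                 n_restarts=2, n_perturbations=2))
frac = summarize_fractions(sel, bound_D_max_um2_s=0.03)
print("K =", sel.K)
print("D (um^2/s) =", np.round(sel.diffusivities, 4))
print("weights    =", np.round(sel.weights, 3))
print("fractions: bound=%.3f confined=%.3f free=%.3f" %
      (frac.fraction_bound, frac.fraction_confined, frac.fraction_free))
```

prints

```
K = 2
D (um^2/s) = [0.0189 0.4895]
weights    = [0.301 0.699]
fractions: bound=0.301 confined=0.000 free=0.699
```

BIC selected two states; the fitted diffusivities land within a few percent
of the ground truth (0.02 and 0.5 µm²/s), the slow-state weight recovers
0.30, and the fraction summary labels the slow state chromatin-bound (no
intermediate confined state exists in this simulation, so the confined
fraction is 0).

The same analysis from the shell, end to end (simulate → states → dwell →
report):

```sh
smt report --config configs/demo.yaml --out runs/demo --seed 1
```

which writes track CSVs, the state model JSON (with the BIC table), posterior
and MSD tables, raw/corrected dwell survival curves, the photobleach model,
the power-law fit (the demo's slow channel carries α = 2 power-law residence
observed through triple-exponential bleaching; the corrected fit returns
α ≈ 2.02), and a run report that reproduces the exact configuration.

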