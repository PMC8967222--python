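# Methods

`smtkit` implements the analysis chain used to characterize transcription-factor
dynamics in live-cell single-molecule tracking (SMT): synthetic trajectory
generation, spot detection and linking, diffusive-state mixture estimation by
perturbation EM (pEM) with BIC model selection, posterior-weighted MSDs and
bound/confined/free fraction summaries, and photobleach-corrected
residence-time analysis. This note records the models, the numerical choices,
and what the synthetic benchmarks do and do not establish.

## Acquisition model

Two acquisition presets mirror the dual imaging strategy used for nuclear
factors such as the glucocorticoid receptor:

| preset | frame interval Δt | exposure t_E | purpose |
|--------|------------------|--------------|---------|
| `fast` | 12 ms (~83 Hz)   | 10 ms        | diffusive-state classification (minimal motion blur) |
| `slow` | 200 ms (5 Hz)    | 10 ms        | residence times (motion-blurs fast molecules away, keeps bound ones) |

Both default to 800 frames. Some published descriptions of this kind of
experiment quote the continuous channel as "12-ms exposures" and others as
"83 Hz with 10-ms exposure"; the two are numerically consistent (83 Hz ≈ 1/12 ms)
and the `fast` preset uses Δt = 12 ms with t_E = 10 ms. The pixel size defaults
to 0.107 µm/px (a typical 150× objective on an EM-CCD) and is configurable
everywhere; no formula hard-codes it.

## Trajectory generator

True motion is Brownian at sub-step resolution (≥ 10 sub-steps per exposure):

* **free**: unrestricted, diffusivity D;
* **confined**: Brownian motion reflected at a hard disk of radius L centred on
  the position where the state was entered. A hard reflecting domain was chosen
  because it gives a closed-form testable MSD plateau (≤ L², the mean squared
  distance of two uniform points in a disk) rather than a soft potential with a
  free parameter;
* **bound**: Brownian with a small D (chromatin jiggle).

State switching is a continuous-time jump process with exponential exit rates
1/mean_dwell and uniform destination choice, discretized at sub-step
resolution. Photobleaching is a per-molecule exponential lifetime; a frame is
recorded only if the molecule survives its entire exposure.

**Motion blur.** The observed position is the average of the sub-step
positions sampled at the *mid-points* of the exposure window, plus isotropic
Gaussian localization noise σ per axis. Mid-point sampling matters: averaging
m positions at mid-points reproduces the continuous-blur displacement variance
2D(Δt − t_E/3) + 2σ² to O(1/m²), whereas endpoint sampling is only O(1/m)
accurate — at m = 10 that error would be comparable to the statistical
resolution of the fidelity tests.

**Effective noise convention.** Throughout the package, per-axis displacement
moments follow the standard blurred-SPT results:

    Var(Δ)            = 2 D Δt + 2 ε²
    Cov(Δ_i, Δ_{i+1}) = −ε²,            ε² = σ² − D t_E / 3

with zero covariance beyond lag 1. The generator is the empirical oracle for
these formulas (the fidelity tests verify them to 3 standard errors).

**Randomness.** All randomness derives from one integer seed through
`SeedSequence` spawn keys tagged per stage, so stages re-run independently and
the same seed yields byte-identical track sets.

**What the generator does not emulate:** focal-plane defocus loss separate
from bleaching, drift, 3D motion, astigmatic PSFs, anomalous (non-Markov)
diffusion, and within-track localization-precision variation. Passing the
benchmarks therefore demonstrates correctness of the estimators under the
stated generative model, not robustness to every artifact of real microscopy
data.

## Detection and linking

Detection: PSF-matched Gaussian filtering, local maxima above
median + k·(1.4826·MAD) of the smoothed frame, sub-pixel refinement by
least-squares 2D Gaussian fit (centroid fallback), duplicate suppression
within one PSF σ keeping the brighter spot.

Linking: per frame pair, an optimal bipartite assignment
(`linear_sum_assignment`) minimizing total squared displacement over candidate
pairs within the maximum displacement — 4 px at 5 Hz and 6 px at ~83 Hz by
default, matching the acquisition design. Optimal (not greedy) assignment is
this package's choice; exact cost ties resolve deterministically by input row
order. No gap closing is performed, tracks shorter than two frames are
discarded, and pixel→µm conversion happens at link time so thresholds stay in
pixels.

Note a physical consequence of the thresholds: at 5 Hz a molecule with
D = 0.5 µm²/s moves ≈ 4.2 px per frame on average, beyond the 4 px limit — the
slow channel by construction tracks only slow/bound molecules, which is its
purpose.

## Diffusive-state mixture (pEM + BIC)

Whole trajectories are classified into K states. Under state k a track's
per-axis displacement sequence is a zero-mean Gaussian with the tridiagonal
covariance above. Log-likelihoods are evaluated with banded Cholesky
factorizations, vectorized over tracks grouped by length; a unit test pins the
banded evaluation to a dense multivariate-normal evaluation at 1e-10 relative
accuracy.

**E-step:** per-track posteriors from the tridiagonal likelihoods.
**M-step:** weights from posterior means; per state, the posterior-weighted
lag-0/lag-1 displacement moments give

    D_k  = (Var_k + 2 Cov_k) / (2 Δt),      ε²_k = −Cov_k

the covariance-based estimator, in which blur and noise cancel exactly.

**Per-state effective noise (design choice).** Because ε² = σ² − D t_E/3
depends on D, the effective noise is genuinely state-dependent — for a fast
state blur can exceed static noise and ε² is legitimately *negative*
(positively correlated adjacent displacements). A single shared ε² is
therefore misspecified whenever states differ in D, and on the canonical
benchmark it biases the slow-state D severely. Per-state ε² is the default;
`shared_noise=True` provides the single-noise variant (ε² pooled and floored
at 0, flagged when floored). Positive definiteness requires ε² > −DΔt/2; the
M-step clamps at −0.49·DΔt and records a warning flag.

**Monotone guard.** The moment M-step is not the exact maximizer of the
structured-covariance Q-function, so each accepted iteration must not decrease
the log-likelihood: if it would, the parameter step is halved toward the
previous iterate (up to 6 times) and the run stops when no improving step
exists. Recorded likelihood histories are therefore non-decreasing
(generalized-EM behaviour), which the test suite asserts over every run.

**Perturbation and restarts.** After convergence (relative log-likelihood
change < 1e-7, cap 500 iterations) the diffusivities are perturbed by
log-normal factors (s.d. 0.3 in log space) and EM re-run, keeping the best of
`n_perturbations` trials per each of `n_restarts` initializations (defaults
10 and 5; the seeded benchmarks use 2 and 2, which the well-separated
benchmark geometry does not strain). Initialization uses quantiles of
per-track covariance-based D estimates; restarts jitter them.

**BIC.** BIC = −2 lnL + p ln(n), with n the total displacement count (the
likelihood's observation unit) and p = 3K − 1 parameters per-state-noise
((K−1) weights + K diffusivities + K noises), or 2K in shared mode.
`select_model` fits every K in range and returns the BIC minimizer along with
the full table.

**Population filter.** A state's population is the fraction of tracks whose
posterior for it exceeds 0.6; states below 5% are discarded, weights
renormalized, and posteriors recomputed from the cached per-track log
densities (the E-step depends on weights only). Refitting the reduced K from
scratch is available as a flag; renormalization is the default.

**Fractions.** States with D ≤ 0.03 µm²/s (default, configurable, echoed in
every summary) form the bound class: the slowest is chromatin-bound, the
remaining bound-class states pool into the confined fraction, everything else
is free. The 0.03 µm²/s default is the order of the apparent-mobility floor
that localization noise imposes on a truly immobile molecule at the fast
protocol.

## Residence-time analysis

Dwell extraction (slow channel): a molecule is bound while every
frame-to-frame displacement is ≤ `bound_radius_um` (default 0.2 µm ≈ the 4 px
slow-channel search radius scaled to µm); maximal bound stretches of ≥ 2
frames become dwell events of duration (frames − 1)·Δt, grouped per cell.
This operational definition is a package choice — the bound criterion is not
standardized — and the radius is swept in tests. Freely diffusing molecules
produce spurious single-step events at the closed-form Rayleigh rate
1 − exp(−r²/2v); they land in the lowest dwell bin and are excluded by the
power-law tail cutoff.

Pooling: the ensemble survival is the track-count-weighted average of
per-cell empirical survivals.

Photobleaching correction: a permanently bound control (histone H2B
analogue) measured under identical acquisition yields the fluorophore
survival, fitted to S_b(t) = Σ A_i exp(−t/τ_i) (≤ 3 components, A_i ≥ 0,
ΣA = 1, least squares on log survival, 10 seeded multi-starts). Two numerical
points: (i) the empirical control curve equals 1 at the smallest *observable*
dwell, i.e. it is left-truncated, so the model is fitted to the conditional
(shape) survival — the correction renormalizes identically, making the
anchoring irrelevant there; (ii) components already extinct at the first
support point are unidentifiable to the shape fit and are dropped with
amplitude renormalization. The corrected survival is
S_corr = S_obs / S_b, renormalized at the smallest observed dwell, clipped to
be non-increasing; division is by the full fitted survival (dividing by a
single selected component is an option). Correction refuses when S_b falls
below 1e-6 on the support. Quantization consistency matters: target dwells
are (frames − 1)·Δt, so the control generator's `quantize="track"` mode uses
the same convention and the quantization bias cancels in the ratio; the
pipeline uses it.

Power-law fit: continuous tail MLE α̂ = 1 + W/Σ w_j ln(t_j/t_min) with the
distribution's probability masses as repetition weights, t_min defaulting to
3 frames (0.6 s at 5 Hz) — tail MLE rather than log-log regression, which is
biased. Frame quantization shifts support values down by up to Δt, biasing α̂
upward by roughly +0.05–0.1 at α = 2; the end-to-end recovery test bounds the
total pipeline error at ±0.15 on the median.

Condition comparison: a two-sample KS statistic on the weighted empirical
CDFs with the asymptotic p-value at effective size n_a·n_b/(n_a+n_b)
(cross-checked against `scipy.stats.ks_2samp` in the unweighted case). The
"paired" wording sometimes attached to this comparison in the literature is
treated as phrasing; the standard two-sample test is what is computed.

## Benchmark conditions

The canonical diffusive-state benchmark is 2,000 tracks × 20 displacements at
the fast protocol with D = 0.02 and 0.5 µm²/s, weights 0.3/0.7, σ = 0.03 µm —
a bound-like and a freely diffusing population at realistic nuclear-TF scales.
The residence benchmark uses power-law residence (α = 2, lower cutoff one
frame) observed through triple-exponential bleaching with amplitudes
0.5/0.3/0.2 and timescales 0.5/2/10 s, 4,000 molecules across 4 cells, and a
5,000-molecule control. Linking benchmarks run 12 molecules in a 30 × 30 µm
field (0.013 spots/µm²). Problem sizes were chosen to give the quoted
statistical resolutions at interactive runtimes.

## Known limitations

* One diffusive state per track: within-track state switching is simulated but
  not inferred (no HMM/vbSPT-style segmentation); switching during a track
  blurs the mixture rather than being labelled.
* The confinement model is a hard disk; real confinement zones are soft and
  mobile.
* The bound/confined/free split keys on diffusivity thresholds and state
  count; it does not use spatial clustering of tracks.
* The KS p-value is asymptotic; for very small samples an exact or
  permutation p-value would be preferable.
* Dwell times are frame-quantized; the continuous tail MLE carries a small
  known upward bias at coarse frame intervals (quantified above).
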