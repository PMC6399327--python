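# Methods

## The measurement being emulated

Receptors in the plasma membrane do not diffuse freely: the cortical actin
meshwork partitions the membrane into microdomains (tens to a few hundred
nanometres across) that transiently corral them, and a receptor escapes a
corral only occasionally ("hop diffusion").  Wide-field SPT movies of
labelled receptors — 20 frames/s, 107 nm pixels, 60–100 s per movie —
yield thousands of 2-D trajectories per condition.  Two per-trajectory
parameters summarize the physics: the diffusivity **D** inside a corral and
the corral's linear size **L**.  Populations are then compared with
standard group statistics and decomposed into diffusive subpopulations.

## Synthetic trajectory generator (`tred.simulate`)

**Model.** A particle carries a hidden state s(t) ∈ {immobile, less_mobile,
mobile}, resampled once per frame from a row-stochastic per-frame
transition matrix.  Within a frame interval Δt the position advances by
`substep_factor` Brownian substeps with per-axis variance 2·D_s·(Δt/substep).
Square corrals of side L_s tile the plane (walls at integer multiples of
L_s); a substep that would cross a wall succeeds with probability
`hop_prob` (the particle enters the adjacent corral) and is otherwise
reflected about the wall.  Reported positions add independent N(0, σ_loc²)
noise per axis.  `simulate_population` groups tracks into synthetic cells
and scales every state diffusivity per cell by 10^ε, ε ~ N(0, s_cell²),
producing the approximately lognormal population spread of D seen in real
per-trajectory estimates.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| Δt | 0.05 s | 20 frames/s acquisition |
| n_frames | 1,200 | 60 s movies |
| substep_factor | 10 | intra-frame confinement is felt; wall crossings per substep stay rare |
| state D | 0.0005 / 0.003 / 0.02 µm²/s | straddles reported per-line means (0.007–0.014 µm²/s) |
| corral L | 0.05 / 0.08 / 0.15 µm | the 40–300 nm microdomain scale; reported L ≈ 80–100 nm |
| σ_loc | 0.02 µm | a typical wide-field localization precision; not a reported value |
| tracks_per_cell | 17 | 15–20 trajectories per cell in the motivating experiments |

Determinism: one `numpy` Generator seeded from the config drives every
draw in a fixed order, so identical configs give bit-identical output.

**What it does not model:** motion blur within an exposure (noise is added
to reported positions only), photobleaching/blinking, camera gain, directed
transport, 3-D motion, endocytosis.  Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under the
assumed physics, not robustness to every artefact of real microscopy data.

`render_stack` converts tracks to image stacks: each particle is an
integrated 2-D Gaussian PSF (error-function differences over pixel edges,
so total signal is conserved), plus constant background, with Poisson
noise.  This supports end-to-end tests of the detection/linking stage.

## Localization and linking (`tred.tracking`)

Spots are local maxima of a difference-of-Gaussians band-pass (0.8×–2× the
PSF SD) exceeding median + `snr_threshold` × 1.4826·MAD of the filtered
frame, refined by least-squares 2-D Gaussian fits in a ±3 PSF-SD window;
fits that fail or leave the window are dropped.  Linking is greedy global
nearest neighbour: all candidate pairs within `max_disp` are sorted by
distance (ties broken by lower track id) and accepted when both ends are
free; a track end may bridge up to `max_gap` missing frames, and bridged
frames remain absent rather than interpolated.  Greedy GNN is adequate at
receptor-tracking densities and is deterministic.  The duration filter
keeps tracks whose time span is ≥ 15 s (inclusive: a track spanning exactly
15.0 s is kept, since only strictly shorter tracks are discarded).

Round-trip accuracy on rendered data: 100% of well-separated particles
(≥ 10 PSF SDs apart) are recovered with mean position error ~3 nm at
6,000 photons/frame (analysis/05).

## MSD computation and the confined fit (`tred.msd`)

The time-averaged MSD of a track is
MSD(nΔt) = mean over index pairs (i, i+n) of (Δx² + Δy²), for
n = 1 … ⌊`max_lag_fraction` × track length⌋ (default 25%; long lags are
noise-dominated).  Missing frames are handled by pairing over frame
differences; an exhaustive double-loop oracle reproduces the vectorized
computation exactly in tests.

**Model form.** The fitted model is the exact eigenmode expansion of
Brownian motion in a square of side L (per axis, summed over both axes):

    MSD(t) = L²/3 − (32·L²/π⁴) Σ_{k odd} k⁻⁴ exp(−k²π²·D·t/L²) + offset.

The familiar single-exponential approximation (L²/3)(1 − e^{−12Dt/L²})
shares the 4Dt short-time slope and the L²/3 plateau but overshoots the
true curve at intermediate lags; when the corral equilibration time L²/12D
is comparable to Δt (as it is at D ≈ 0.01 µm²/s, L ≈ 0.1 µm, Δt = 0.05 s)
fitting it against simulated square-corral data biases D low by about 20%.
The exact series (100 odd modes; truncation error < 0.3% on the slope)
removes that bias: median fitted D and L land within ~3% and ~1% of the
generating values on the recovery fixture.  The `offset` (constrained ≥ 0)
absorbs the localization-noise floor: independent per-frame noise of SD σ
adds 4σ² to every MSD value, and the fitted offset recovers ≈ 4σ² in
simulation while leaving D within 10%.

**Fitting.** Weighted nonlinear least squares (weights = pair counts, which
fall with lag); D initialized from the OLS slope of the first three lags
(slope/4, clipped ≥ 1e-6 µm²/s), L from √(3·max MSD), offset at 0.  Lags
with fewer than 10 pairs are excluded and ≥ 4 lags must remain.  A fit is
flagged non-converged when the optimizer fails or the fitted L exceeds 10×
the largest RMS displacement on the curve (plateau not identified — e.g.
free diffusion).  Non-converged fits are excluded from downstream means
rather than replaced by a linear fallback, keeping the D population
unbiased; the exclusion count is logged.  The short-lag slope estimate is
kept as a diagnostic alongside the corral-model D.  L is stored in µm and
reported in nm (×1000) at the interface layer.

## Population statistics (`tred.stats`)

Per-trajectory D and L are approximately lognormal, so mixtures are fitted
to log₁₀ values by EM (scikit-learn `GaussianMixture`: 10 seeded restarts,
variance floor 1e-4 in log₁₀² units) for K in 1–3 (D) or 1–2 (L), and the
K minimizing AIC = 2p − 2·loglik (p = 3K − 1) is kept.  Components are
sorted by log-mean and labelled immobile/less_mobile/mobile (K = 3) or
small/large (K = 2).  Arithmetic moments per component follow the exact
lognormal identities with a = ln 10:

    mean = exp(a·µ + a²σ²/2),   sd = mean·√(exp(a²σ²) − 1).

Group comparisons follow the F-test-gated convention: a two-sided F-test
on the variance ratio at α = 0.05 selects the pooled-variance t-test (F-test
not significant) or Welch's t-test with Satterthwaite df.  Degenerate
zero-variance groups use p = 1 (equal means) / p = 0 (unequal) by
convention.  Percent differences, 100·(x − ref)/ref, are rounded to integer
percent in reports (figures print integers); the unrounded value is kept
internally.  Pearson correlation relates per-condition mean D to an
external per-condition score vector (e.g. a gene-expression-derived
differentiation score, consumed as a plain table — its computation is out
of scope).

## Diffusive-state HMM (`tred.hmm`)

Per-frame displacement vectors are modelled as a K-state HMM: state i emits
two independent zero-mean Gaussian components with variance 2·Dᵢ·Δt
(a spherical 2-D Gaussian), and states evolve with per-frame transition
matrix P.  Parameters are estimated by Baum–Welch jointly over all
trajectories (tracks with internal gaps are split into contiguous
segments); 5 seeded restarts keep the best log-likelihood, and EM stops at
relative loglik change < 1e-8 or 500 iterations.  The per-iteration
log-likelihood history is recorded and its monotonicity asserted.  The
number of states is chosen by BIC = p·ln(N_steps) − 2·loglik with
p = K + K(K−1) + (K−1).  Reported quantities: D per state (ascending),
P (row-stochastic), occupancy as the stationary distribution of P, dwell
times τᵢ = Δt/(1 − Pᵢᵢ), and Viterbi state paths.  This maximum-likelihood
treatment replaces the variational-Bayes estimator often used for SPT state
analysis (vbSPT): same emission and Markov structure, simpler estimator,
same report format.

Implementation rests on hmmlearn with two local adjustments: a subclass
forces the posterior-count statistics to accumulate when means are frozen
at zero (hmmlearn otherwise skips them and the covariance update divides by
zero), and a convergence monitor implements the relative stopping rule.

**Noise floor.** Localization noise is deliberately not part of the
emission model (matching common practice).  A static particle observed with
per-axis noise SD σ produces displacements of variance 2σ², so the fitted D
of the slowest state is bounded below by σ²/Δt — 0.008 µm²/s at σ = 20 nm
and Δt = 0.05 s.  On noisy data the immobile and less-mobile generative
states therefore merge into one floor state; state structure below the
floor is only resolvable on noiseless or low-noise data.

**Windowed transitions.** To expose time dependence (e.g. after a stimulus)
trajectories are cut at window boundaries (default five 20-s windows over
100 s) and only P (and the initial distribution) is re-fitted per window,
with emissions frozen at the global model's diffusivities so state labels
cannot switch between windows.  P(mobile → less_mobile) per window is
reported.

## Pipeline and artifacts (`tred.pipeline`, `tred` CLI)

Stages simulate/track → msd → popfit → hmm → report run in dependency
order; every intermediate (tracks CSV, estimates CSV, report JSON, model
JSON, TIFF stacks) is persisted so each reported number is recomputable
from disk.  Reports carry a provenance block (config hash, package version,
seed) and the three-tier significance convention (*** p<0.001, ** p<0.01,
* p<0.05).  Re-running with the same config and seed reproduces
byte-identical CSV/JSON artifacts.

## Problem sizes used in tests and the acceptance script

Recovery checks use 200 tracks × 2,000 frames (MSD), 20 seeds × n = 3,000
(mixtures), 10⁵ displacement steps (HMM), and 1,000 replicates (type-I
calibration); multi-seed property tests use smaller per-seed fixtures
(30 × 800 frames; 20 × 500 frames) where the median across seeds is the
tested statistic.  These sizes give sampling error comfortably below the
asserted tolerances.

## Known limitations

- The simulator's corral grid is axis-aligned and global; real meshworks
  are irregular.  Corral geometry changes discontinuously at state
  switches.
- Whole-track confined fits on state-switching trajectories measure an
  occupancy-weighted effective (D, L), not per-state values; with 60-s
  tracks and fast switching the log₁₀D population can appear unimodal even
  when three generative states exist.  The analysis drivers therefore use
  state dwell times long relative to track length when demonstrating
  subpopulation decomposition.
- Whether receptor immobilization reflects binding (D = 0) or tight
  confinement is not resolved by the assay; the simulator supports either.
- No multiple-testing correction is applied to the pairwise test matrix,
  matching the conventions of the assay this package reimplements.
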