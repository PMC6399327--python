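# tred — Transmembrane Receptor Dynamics

Single-particle-tracking (SPT) analysis of membrane-receptor dynamics, built
around the TReD phenotyping idea: the lateral mobility of a transmembrane
receptor (here EGFR is the motivating example) reports on the cortical-actin
meshwork that corrals it, and two numbers extracted per trajectory — the
diffusivity **D** (µm²/s) and the linear confinement size **L** (nm) —
separate cell populations by phenotype (epithelial vs. mesenchymal,
non-invasive vs. highly invasive).

The package provides the full computational pipeline plus a synthetic
hop-diffusion generator, so every stage is testable without microscope data:

1. **`tred.simulate`** — corral-confined hop diffusion (Kusumi-style
   picket-fence model) with Markovian switching between diffusive states
   (immobile / less mobile / mobile), per-cell lognormal heterogeneity,
   localization noise, and rendering of trajectories into TIFF stacks.
2. **`tred.tracking`** — spot detection (DoG band-pass + sub-pixel 2-D
   Gaussian fits), greedy global-nearest-neighbour linking with optional gap
   bridging, and the ≥ 15 s track-duration filter.
3. **`tred.msd`** — time-averaged MSD per trajectory and the confined-
   diffusion fit.  The model is the exact square-corral MSD

   MSD(t) = L²/3 − (32 L²/π⁴) Σ_{k odd} k⁻⁴ e^{−k²π²Dt/L²} + offset,

   with short-time slope 4Dt, plateau L²/3, and a constant offset absorbing
   the localization-noise floor (≈ 4σ²).
4. **`tred.stats`** — Gaussian-mixture fits of log₁₀D (1–3 components) and
   log₁₀L (1–2) selected by AIC, lognormal → arithmetic moment conversion,
   mean ± SEM summaries, F-test-gated unpaired t-tests (pooled vs. Welch),
   percent differences and Pearson correlation against an external score
   vector.
5. **`tred.hmm`** — a diffusive-state hidden Markov model over per-frame
   displacements (state i emits zero-mean Gaussian steps with per-axis
   variance 2·Dᵢ·Δt), fitted by Baum–Welch with BIC state-count selection;
   reports transition matrix P, occupancies π, dwell times τᵢ = Δt/(1−Pᵢᵢ),
   Viterbi paths, and windowed re-estimates of P(mobile → less mobile).
6. **`tred.pipeline` / `tred` CLI** — end-to-end orchestration
   (simulate/track → msd → popfit → hmm → report) with persisted
   intermediates, significance stars, and figure generation.

## Worked example

```python
import numpy as np
from tred import (SimulationConfig, StateSpec, simulate_tracks,
                  estimate_all, fit_states, percent_difference)

cfg = SimulationConfig(n_tracks=200, n_frames=2000,
                       states=[StateSpec("confined", 0.01, 0.1)],
                       loc_noise_sd=0.0, seed=101)
est = [e for e in estimate_all(simulate_tracks(cfg)) if e.converged]
print(np.median([e.D for e in est]))    # 0.009673  (truth 0.01 µm²/s)
print(np.median([e.L_nm for e in est])) # 99.12     (truth 100 nm)

# the assay's comparison statistic, on published group means
print(percent_difference(0.0112, 0.0081, rounded=True))  # 38.0 (%)
```

The numbers printed above are what the code produces at these seeds: the
confined-model fit recovers the generating diffusivity to ~3% and the
corral size to ~1% from 200 noiseless 100-s tracks, and the percent
difference of two group means is reported as the integer percent used in
figures.

The `analysis/` directory holds numbered narrative drivers that run the
whole assay over three simulated conditions (epithelial-like, EMT-induced,
mesenchymal-like): `01_simulate_conditions.py`, `02_fit_msd.py`,
`03_population_stats.py`, `04_state_hmm.py`, `05_tracking_roundtrip.py`.
Each writes its tables and figures under `results/analysis/` and prints
what it found.

## Documentation

`docs/methods.md` describes the generative model, the fitted models and
their assumptions, parameter defaults with units, numerical choices, and
known limitations.
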