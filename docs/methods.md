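# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `stormssm`.

## Problem setting

A fixed array of ~40 acoustic receivers monitors tagged juvenile white
sharks in a shallow nursery (receivers 300–500 m apart in 5–15 m of water,
covering a few km² of nearshore habitat). Half the receivers house internal
sync tags (nominal transmission delay 540–660 s); animal tags transmit every
150–250 s. The analysis window is hourly over 41 days (984 bins) spanning a
24-h storm. Two confounded processes must be separated: storm-driven
emigration of animals from the array footprint, and storm-driven degradation
of the array's ability to detect animals that remain.

## Stage 1: sync-tag detection efficiency

Hourly binary outcomes for each admissible (sync tag, receiver) pair follow
a Bernoulli–logit regression with a free pair intercept
`alpha_ij ~ Uniform(-4, 4)` (logit scale) and slopes `~ Normal(0, sd 1)` for
log distance, receiver depth, wind, significant wave height, ambient noise,
receiver tilt and the hourly count of animals detected (a proxy for
code-collision pressure). Covariates are standardized to mean 0, unit
sample variance (n−1 denominator); distance is log-transformed *before*
standardization. Admissible pairs exclude self-pairs (a receiver hearing its
own internal tag is at distance 0, where the log transform is undefined) and
by default pairs beyond 800 m, where the detection probability is
negligible; both choices are configurable.

**Identifiability.** With a free intercept per pair, the pair-constant
covariates (log distance, depth) are collinear with the intercepts: they are
informed only through the intercepts' bounded support and their own priors.
The time-varying slopes are fully identified. We report all seven slopes but
treat distance/depth estimates as weakly identified; only the five
time-varying slopes are exported as transfer priors, so this weakness never
propagates to stage 2. The sampler handles the resulting posterior ridge
with a dedicated translation move (shift a pair-constant slope while
compensating all intercepts one-for-one; the likelihood cancels exactly and
the move is accepted on the prior ratio alone — a linear map with unit
Jacobian), without which the marginal posteriors of `b_dist`/`b_depth` mix
far too slowly to be usable.

**Counterfactual detection curves.** Population-level curves evaluate, per
posterior draw, `logistic(mean_pairs(alpha) + b_dist z(log d) + b_depth
z_depth + Σ b_x x_cond)` over a distance grid, with depth at the array mean
(z = 0). Condition values are per-covariate means of the standardized series
over non-storm hours (baseline) and over the 24-h storm window (storm); the
animal-count covariate is held at its overall mean in both conditions so the
curves isolate environmental effects.

## Stage 2: occupancy state-space model

Hourly presence `Z[i,t] ∈ {0,1}` evolves as a first-order Markov chain:
leaving hazard `phi_emig[i,t]` (logit-linear in the six environmental
predictors — wind, waves, barometric pressure, SST, salinity, turbidity — a
sine/cosine diel pair over the 24-h day, and a shark-level random intercept
`alpha_i ~ N(mu_a, sigma_a²)`), and a constant return probability
`phi_return = logistic(alpha_return)`. Priors: `mu_a ~ N(0, 2²)`,
`tau_a = sigma_a^-2 ~ Gamma(1, 1)`, `alpha_return ~ N(0, 2²)`, all slopes
`~ N(0, 2²)`.

Detections are zero-forced: `y[i,j,t] | Z ~ Bernoulli(Z · p_det[j,t])`, so
any detection pins presence with probability exactly 1. Receiver baselines
`theta_j ~ Beta(1, 1)` enter on the logit scale; the observation slopes for
wind, waves, noise, tilt and animal density carry the stage-1 transfer
priors `N(mu_sync, sigma_sync²)`. A degenerate transfer prior (sd = 0) is
rejected at load, since it would freeze an observation slope. The reduced
variant drops the observation slopes entirely (constant per-receiver
detection), and comparing its state-process posteriors against the full
variant quantifies how much the detection correction mattered.

**Inference.** The default sampler marginalizes the latent chain exactly:
each likelihood evaluation runs a log-space forward recursion over the two
states per animal (numba-compiled; validated to 1e-10 against exhaustive
enumeration over all 2^T paths on small instances). Parameter updates are
adaptive random-walk Metropolis within Gibbs — vectorized per-animal
intercept updates (conditionally independent), conjugate Gibbs for
`mu_a`/`tau_a`, coordinate-wise updates for the state slopes and observation
slopes, and small joint blocks (4 receivers) for the baselines. Latent
decoding uses forward–backward smoothing averaged over a subsample of
posterior draws (default 200; detection hours are set to exactly 1). An
alternative data-augmentation sampler (forward-filter/backward-sample the
chain, then conditional updates, with conjugate Beta draws for the reduced
variant's baselines) targets the identical posterior and is cross-checked
against the marginal sampler in the tests. Rationale for the marginal
default: it avoids sampling ~500k discrete states at study scale and its
correctness is directly checkable against the enumeration oracle.

The initial state is `P(Z[i,1] = 1) = 0.5` (uninformative, configurable).
Hours where an animal is detected only outside the modelled array count as
non-detections: "absent" means absent from the array footprint.

## MCMC engine

Defaults mirror the study protocol: 3 chains × 10,000 iterations, burn-in
1,000, thinning 10 → 900 retained per chain, 2,700 total (retained count is
exactly `floor((n − burn) / thin)`; the last iteration of each thinning
group is kept). Chains derive independent generators from the master seed
via `SeedSequence(seed, spawn_key=(chain,))`, making every run bit-for-bit
reproducible. Proposal scales adapt by Robbins–Monro
(`scale *= exp(k^-0.66 (accept − target))`) during burn-in only and are
frozen afterwards, preserving detailed balance in the retained phase.
Convergence uses the classical Gelman–Rubin statistic
`sqrt((((n−1)/n) W + B/n) / W)` (split-chain variant available), threshold
1.05; effective sample size uses the initial-positive-sequence estimator.
Posterior quantiles interpolate linearly between order statistics (the
2.5/50/97.5 percentiles define the reported intervals).

## Synthetic-data generator

The generator is the package's study stand-in and single source of truth for
what "the study conditions" mean. Geometry: a jittered grid sized to the
configured receiver count with nearest-neighbour spacing held inside the
configured range (default pitch 470 m ± 12 m jitter for the 300–500 m
range). A 40-receiver grid with spacing capped at 500 m cannot exceed a
~7 km² convex hull, so the generator's ~6 km² footprint is taken as the
array-proper area, with published "~10 km²" coverage figures understood to
include detection-range buffer. Depths follow a cross-shore gradient over
5–15 m. Every other receiver carries a sync tag.

Environment: smooth baselines with AR(1) noise plus a parametric storm pulse
— a barometric trough preceding a 22 m/s (~80 km/h) wind peak, a 6 °C SST
drop over 12 h with a ~1-week exponential recovery, a modest wave-height
rise, a salinity crash from 33.5 psu toward ~1 psu at peak runoff, a
turbidity spike, and elevated receiver noise/tilt. All amplitudes are
configurable and may be zeroed (stationary control). Per-receiver
diagnostics are the array series plus receiver offsets and noise, and are
re-averaged by the ingestion code, exercising that path end-to-end.

State truth defaults encode the study regime: baseline hourly emigration
≈ 0.01 (`mu_a = −4.5`), `sigma_a = 0.3`, a strongly negative SST effect
(−1.2) dominating, small pressure/salinity/wave effects (−0.15, −0.05,
+0.1 — small per standardized unit because those covariates' storm
excursions span many sd), near-zero wind/turbidity effects,
`phi_return = 0.05`, initial presence 0.9. With the simulated SST profile
(storm minimum ≈ 3σ below the window mean) this implies a storm-peak
emigration hazard of roughly 0.3–0.6 against a ~0.008 baseline.
Observation truth: `theta_j ~ Beta(2, 4)` baselines and uniformly negative
detection slopes with noise, tilt and animal density strongest — with ≥ 16
receivers this reproduces the high observational redundancy of the real
array (a present animal is almost never silent for a whole hour on every
receiver at once). Sync truth: pair intercepts `U(−1.7, 0.3)` and
`b_dist = −0.5`, `b_depth = +0.4`, calibrated so the implied baseline
detection-vs-distance curve passes near 0.99 at 100 m and 0.55 at 400 m on
the default array's standardized scale; the time-varying slopes (noise and
tilt strongest) are sized so the implied storm-vs-baseline shift is about
−0.6 logit — detection barely moves at short range but drops substantially
at long range, the signature the detection-efficiency correction exists to
catch.

The animal-density covariate is circular in a generator (detections depend
on it, it is computed from detections), so the generator uses the *true*
hourly presence count; the fitting pipeline recomputes it from observed
detections, as a real study must. With high redundancy the two are nearly
identical. Detections are simulated at the hourly-binary modelling
resolution; record expansion (for the CSV interchange format) draws
per-transmission-like counts from the nominal delay budget and uniform
within-hour times, and is a formatting convenience, not a collision model.

What the generator does *not* emulate: acoustic propagation physics and
range-test structure, code collisions, tides, spatially continuous animal
tracks, inter-covariate correlation beyond what the shared storm pulse
induces, and non-storm sensor failure. Passing recovery tests therefore
shows the inference machinery is correct and well calibrated under the
model, not that the model captures every feature of field data.

## Recovery experiments and test scales

The suite exercises recovery at reduced problem sizes chosen to keep a full
run within a normal development budget: the sync model at 20 tags × 20
receivers × 1,000 h with 5 replicates (95% CI coverage ≥ 4/5 per slope;
mean bias of the identified, time-varying slopes < 0.1 standardized units),
and the occupancy model at 10 animals × 500 h × 16 receivers with 10
replicates (sign of the planted SST effect recovered in ≥ 9/10; pooled CI
coverage of the state-process slopes ≥ 80%). Recovery fits use 2 chains of
2,000–2,200 iterations; the engine's defaults remain the full study
protocol. The end-to-end pulse check plants an exactly 10× emigration pulse
(the SST slope is solved against the simulated SST z-profile so the true
hazard ratio between the storm peak and the non-storm median is 10) in a
scenario designed for identifiability — a single storm covariate, a tight
random intercept, and a high return probability (0.4) so animals re-expose
themselves to the hazard during the pulse, keeping the storm-side event
count well above the single-evacuation ceiling — and requires the
pipeline-reported fold change to land in [9, 11]. The reproduction script
(`scripts/acceptance.py`) runs its full two-stage analysis on a
half-size-array study (20 receivers, 10 sync tags, 16 animals) over the
complete 984-h window with 2 chains of 3,000 iterations per stage.

## Reporting definitions

- *Emigration series*: per hour, the 2.5/50/97.5 percentiles over draws of
  `phi_emig` evaluated at the population intercept `mu_a` (per-animal series
  use each `alpha_i`). Evaluating at `mu_a` (the typical animal) rather than
  integrating over `sigma_a` is the documented default; both are exposed.
- *Overall emigration probability*: the median (and central 95% interval) of
  the pooled draws × animals × hours array of `phi_emig`, subsampled to 300
  draws for memory.
- *Fold change*: the maximum hourly median divided by the median of hourly
  medians over non-storm hours (the complement of the declared storm
  window); the definition string travels with the output.
- *Age cohorts*: von Bertalanffy ages (defaults `L_inf = 763.7 cm`,
  `k = 0.058 /yr`, `t0 = −3.53 yr`, calibrated once so the bundled tagging
  table's reported ages are reproduced to ±0.1 yr) binned by integer year
  into 1–2 vs 3–4 groups.
- *Variant comparison*: paired posterior summaries of all shared
  state-process parameters; a parameter is flagged when the medians differ
  by more than half the full model's posterior sd.

## Numerical choices

- Hour bins are left-closed, right-open, UTC; the diel covariate uses local
  hour with a configurable UTC offset (default −7).
- Missing covariate or diagnostic hours are linearly interpolated up to 6
  consecutive hours (configurable); longer gaps are a hard error.
- Distances are planar Euclidean; lon/lat input is projected
  equirectangularly about the array centroid (sub-kilometre arrays make the
  projection error negligible).
- Log-space forward recursion uses a −1e30 sentinel for impossible states
  and pairwise log-sum-exp; zero-forced hours are additionally set to
  exactly 1 when decoding.
- Standardization records (mean, sd) are stored per column and invert the
  transform to 1e-9, enabling back-transformation of coefficients.
- Empirical-logit initial values for intercept-like parameters are clipped
  to (−3.9, 3.9) inside the uniform bounds.
- Tag-family power differences (V13 vs V16) are ignored: one shared
  observation model, matching the analysis design.

## Known limitations

- `b_dist`/`b_depth` are structurally weakly identified (above); their
  posteriors should be read as bounded summaries, not effect estimates.
- The environmental covariates co-move during a single storm, so individual
  state slopes are partially confounded at small sample sizes; intervals are
  honest about this (coverage holds) but point estimates shuttle probability
  mass between correlated storm predictors. With few animals and extreme
  covariate excursions the *peak* of the emigration series — a max over
  saturating logistic curves — can overshoot; study-scale data constrain it.
- `phi_return` is constant by design; no covariates on the return process
  and no seasonal drift.
- No model-selection statistics for the full-vs-reduced comparison; the
  comparison is deliberately descriptive.
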