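# stormssm

Storm-response occupancy modelling for acoustic telemetry arrays.

When a storm hits a coastal acoustic receiver array, two things happen at
once: tagged animals may genuinely leave, and the receivers get worse at
hearing the animals that stay (wind, waves and ambient noise all degrade
acoustic detection). Any analysis that reads raw detection counts during a
storm therefore confounds behaviour with instrument failure. `stormssm`
implements a two-stage Bayesian pipeline that separates the two, built for
the canonical use case of juvenile white sharks evacuating a Southern
California nursery during an August 2023 tropical storm, and applicable to
any fixed array with internal synchronization ("sync") tags.

## The model

**Stage 1 — detection efficiency from sync tags.** Each receiver's internal
sync tag is a transmitter at a known, fixed location, so its hourly
detections on neighbouring receivers probe array performance continuously.
For sync tag *i*, receiver *j*, hour *t*:

    y_sync[i,j,t] ~ Bernoulli(p_sync[i,j,t])
    logit p_sync = alpha_ij + b_dist log DIST_ij + b_depth DEPTH_j
                   + b_wind WIND_t + b_waves WAVES_t + b_noise NOISE_t
                   + b_tilt TILT_t + b_sharks SHARKS_t

with pair intercepts alpha_ij ~ Uniform(-4, 4) on the logit scale and slopes
~ Normal(0, 1); all covariates standardized.

**Stage 2 — latent occupancy with transferred priors.** Each animal's hourly
presence Z[i,t] in the array is a hidden two-state Markov chain,

    Z[i,t] | Z[i,t-1] ~ Bernoulli(psi),   psi = 1 - phi_emig[i,t]  if present
                                          psi = phi_return         if absent
    logit phi_emig = alpha_i + b_sin sin(2πh/24) + b_cos cos(2πh/24)
                     + b·(WIND, WAVES, BARO, SST, SAL, TURB)_t

with a shark-level random intercept alpha_i ~ N(mu_a, sigma_a²). Detections
are conditional on presence (an absent animal cannot be detected):

    y[i,j,t] | Z[i,t] ~ Bernoulli(Z[i,t] · p_det[j,t])
    logit p_det = logit(theta_j) + b_det·(WIND, WAVES, NOISE, TILT, SHARKS)_t

where each observation slope gets an *informative* prior
`Normal(mu_sync, sigma_sync²)` — the posterior mean and sd of the matching
slope from stage 1. That prior transfer is the methodological point: the
occupancy estimates are corrected for storm-driven detection loss. A reduced
variant (constant per-receiver detection) quantifies how much the correction
mattered.

Inference is adaptive Metropolis-within-Gibbs with the latent chain
marginalized exactly by a log-space forward algorithm (a data-augmentation
sampler via forward-filter/backward-sampling is included as a cross-check).
The default protocol runs 3 chains × 10,000 iterations, discards 1,000 as
burn-in and retains every 10th draw (900/chain, 2,700 total), with
convergence declared at Gelman–Rubin R-hat < 1.05.

## Worked example

`examples/` contains one short script per capability. The core loop —
simulate a storm study with known truth, fit both stages, recover the
emigration drivers (`examples/03_occupancy_fit.py`) — prints:

```
convergence: max R-hat 1.043 (passed=True)

state-process posteriors (logit scale) vs generating truth:
  mu_a         -4.363  [-4.938, -3.799]   truth -4.500
  alpha_return -3.121  [-3.406, -2.852]   truth -2.944
  beta_sst     -1.134  [-1.534, -0.725]   truth -1.200
  beta_baro    -0.380  [-0.752, -0.003]   truth -0.150
  ...
decoded presence matches simulated truth at 100.0% of animal-hours
detection hours are pinned to presence probability exactly 1: True
```

Read it like this: `mu_a` ≈ −4.4 on the logit scale means a typical animal
had about a 1% chance of leaving the array in a calm hour; the strongly
negative `beta_sst` with an interval excluding zero says falling sea-surface
temperature — not detection loss — drove the disappearances; and the decoded
latent states recover the simulated truth at every animal-hour here.
`examples/04_emigration_report.py` condenses the same fit into the headline
numbers — baseline emigration median 0.011, storm peak 0.288, a 26.5-fold
increase:

```
overall emigration probability (pooled draws x animals x hours): median 0.0110 [0.0010, 0.1759]
peak hourly emigration median: 0.288 at 2023-08-09 04:00:00+00:00
baseline (non-storm) median: 0.0108
fold change: 26.5x   (max hourly median / median of hourly medians over non-storm hours)
```

The same pipeline runs from the shell:

```bash
stormssm simulate --out data --seed 1
stormssm fit-sync --data data --out sync --seed 1
stormssm fit-ssm --data data --transfer-prior sync/transfer_prior.json \
                 --out ssm --seed 1
stormssm report --fit ssm --data data --out report
```

Every output directory carries a `manifest.json` (config echo, input hashes,
seeds, convergence flags), so runs are reproducible bit-for-bit from the
master seed.

## Layout

- `src/stormssm/telemetry_io.py` — detection logs → hourly binary matrices;
  covariate table with standardization records; pair geometry; growth-curve ages
- `src/stormssm/sync_efficiency.py` — stage-1 regression, counterfactual
  detection curves, transfer-prior export
- `src/stormssm/occupancy.py` — stage-2 state-space model, forward
  marginalization, latent decoding, both samplers
- `src/stormssm/mcmc.py` — adaptive Metropolis engine, Gelman–Rubin, summaries
- `src/stormssm/simulate.py` — synthetic storm studies with known truth,
  recovery experiments
- `src/stormssm/reporting.py` — emigration series, fold change, occupancy
  counts, full-vs-reduced comparison
- `src/stormssm/pipeline.py`, `cli.py` — composable commands + thin CLI
- `docs/methods.md` — model details, assumptions, numerical choices, limits
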