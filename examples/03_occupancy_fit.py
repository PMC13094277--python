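"""Fit the occupancy state-space model with transfer-informed detection.

The latent two-state chain (present/absent, with covariate-driven emigration
and constant return probability) is marginalized exactly by the forward
algorithm each likelihood evaluation; the observation layer's covariate
slopes carry the informative priors exported by the sync-tag model.
"""

import numpy as np

from stormssm.mcmc import McmcConfig, posterior_summary
from stormssm.occupancy import fit_ssm
from stormssm.simulate import ScenarioConfig, simulate_study
from stormssm.sync_efficiency import export_transfer_priors, fit_sync_model

config = ScenarioConfig(n_receivers=16, n_sync_tags=8, n_animals=10,
                        window_hours=400, storm_start_hour=180, seed=1)
study = simulate_study(config)

mcmc = McmcConfig(n_chains=2, n_iterations=2000, burn_in=800, thin=3, seed=2)
sync_fit = fit_sync_model(study.sync_matrix, study.covariates, study.geometry,
                          mcmc_config=mcmc)
transfer = export_transfer_priors(sync_fit)

fit = fit_ssm(study.animal_matrix, study.covariates, transfer,
              variant="full", mcmc_config=mcmc)
print(f"convergence: max R-hat {fit.convergence.max_rhat:.3f} "
      f"(passed={fit.convergence.passed})")

print("\nstate-process posteriors (logit scale) vs generating truth:")
truth = {
    "mu_a": config.state_truth.mu_a,
    "alpha_return": config.state_truth.alpha_return,
    **{f"beta_{n}": getattr(config.state_truth, f"beta_{n}")
       for n in ("sst", "baro", "sal", "waves", "wind", "turb")},
}
for name, t in truth.items():
    s = posterior_summary(fit.samples, name)
    print(f"  {name:12s} {s['median']:+.3f}  [{s['lower95']:+.3f}, {s['upper95']:+.3f}]"
          f"   truth {t:+.3f}")

# decoded latent occupancy vs the simulated truth
agree = ((fit.occupancy > 0.5) == (study.z_true == 1)).mean()
print(f"\ndecoded presence matches simulated truth at {agree:.1%} of animal-hours")
print("detection hours are pinned to presence probability exactly 1:",
      bool(np.all(fit.occupancy[study.animal_matrix.values.any(axis=1)] == 1.0)))

# A strongly negative SST slope with intervals excluding zero is the model's
# way of saying the cold pulse, not detection loss, drove the disappearances.
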