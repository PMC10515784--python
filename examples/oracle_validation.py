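"""Validate the sampler against exact Boltzmann quadrature (1 base pair).

For a single A·T pair the equilibrium distribution on the bounded domain
can be integrated numerically; the Metropolis estimate of the mean opening
and of the opening probability must agree within run-to-run Monte-Carlo
error.  The same check is available for any custom parameter file.
"""

import math

import numpy as np

import epbdsim as E

params = E.EPBDParameters.default()
sp = E.single_bp_site_params(params, "AT")
bounds = (sp.y_min, sp.y_max)

schedule = E.MCMCSchedule(
    temperature=310.0, preheat_steps=200_000, measure_steps=20_000,
    record_interval=10, n_runs=20, base_seed=3,
)
ensemble = E.run_ensemble(None, None, schedule, site_params=sp)

mean_runs = ensemble.per_run_means()[:, 0]
flip_runs = ensemble.per_run_flipping(1.5)[:, 0]
se_mean = mean_runs.std(ddof=1) / math.sqrt(20)
se_flip = flip_runs.std(ddof=1) / math.sqrt(20)

oracle_mean = E.boltzmann_average_1bp(sp.D[0], sp.a[0], 310.0, bounds, lambda y: y)
oracle_open = E.opening_probability_1bp(sp.D[0], sp.a[0], 310.0, bounds, 1.5)

print(f"<y>      MCMC {mean_runs.mean():.3f} ± {se_mean:.3f} Å   quadrature {oracle_mean:.3f} Å")
print(f"P(y>1.5) MCMC {flip_runs.mean():.3f} ± {se_flip:.3f}     quadrature {oracle_open:.3f}")
print(
    "\nAn isolated base pair on the bounded domain is mostly open at 310 K "
    "(the\nMorse plateau dominates); stacking in a chain is what keeps real "
    "DNA closed.\nAgreement within ~3 standard errors validates the sampler."
)
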