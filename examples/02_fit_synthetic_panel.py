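"""Fit MCPGIGR and the multivariate Poisson baseline to one synthetic panel.

Simulates n=300 units at the built-in study truth (bivariate responses, two
U(0,10) predictors, unit exposures), fits both models by BHHH, and prints
estimates, standard errors and the AICc comparison.
"""

import numpy as np

from mcpgig import aicc, fit_mcpgigr, mpr_fit
from mcpgig.simulate import default_truth, generate_design, simulate_dataset

truth = default_truth(-0.5)
rng = np.random.default_rng(2024)
panel = simulate_dataset(generate_design(300, seed=rng), truth,
                         family="MCPGIG", seed=rng)
print(f"panel: n={panel.n}, m={panel.m} responses, p={panel.p} predictors")
print(f"response means {panel.responses.mean(0).round(3)}, "
      f"variances {panel.responses.var(0).round(2)} (heavy overdispersion)")

fit = fit_mcpgigr(panel, gamma=-0.5)
print(f"\nMCPGIGR: converged={fit.converged} in {fit.iterations} iterations, "
      f"loglik={fit.loglik:.2f}")
print(f"{'parameter':>10} {'true':>8} {'estimate':>9} {'se':>8}")
names = [f"beta_{j + 1}{k}" for j in range(2) for k in range(3)]
for name, true, est, se in zip(names, truth.betas.ravel(),
                               fit.estimates.betas.ravel(), fit.se):
    print(f"{name:>10} {true:8.3f} {est:9.3f} {se:8.3f}")
print(f"{'tau':>10} {truth.gig.tau:8.3f} {fit.estimates.gig.tau:9.3f}")
print(f"{'xi':>10} {truth.gig.xi:8.3f} {fit.estimates.gig.xi:9.3f}")
print("(tau and xi are reported on the natural scale; only their combination")
print(" omega = sqrt(tau^2 + xi^2) - xi is identified, see docs/methods.md)")

mpr = mpr_fit(panel)
print(f"\nMPR baseline: loglik={mpr.loglik:.2f}")
print(f"AICc: MCPGIGR {aicc(fit):.2f}  vs  MPR {aicc(mpr):.2f} "
      "-> the mixture wins decisively on overdispersed data")
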