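"""Recover a population of interaction rates from fully observed dynamics.

Simulates 100 cells of a 16-species generalized Lotka-Volterra ring in which
four tied inhibition rates vary across the population (mean 0.02, SD 0.005),
then infers the population distribution by spline-based gradient matching
plus EM, without integrating a single ODE during estimation.
"""

import numpy as np

from gmgts import fit_gmgts, generate_scenario, recovery_report

ds = generate_scenario("lotka_volterra_full", seed=1)
res = fit_gmgts(ds)

b = res.population.b_hat
sd = np.sqrt(np.diag(res.population.D_hat))
print("recovered mean rates:", np.round(b, 5), " (generating value 0.02)")
print("recovered rate SDs:  ", np.round(sd, 5), " (generating value 0.005)")

report = recovery_report(res.population, ds.generating_distribution,
                         runtime_seconds=res.runtime_seconds)
print(f"normalized W2 distance to the generating distribution: "
      f"{report.w2_normalized:.4f}")
print(f"runtime: {res.runtime_seconds:.1f} s for {ds.N} cells")
# The W2 score aggregates mean and covariance mismatch; values well below 1
# mean the recovered distribution is close relative to the mean rate itself.
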