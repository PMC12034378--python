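# gmgts — gradient-matching two-stage inference for heterogeneous cell populations

Single-cell time series from isogenic populations show substantial
cell-to-cell variability.  When the intracellular process is well described
by a deterministic ODE, that variability is naturally modeled by letting
each cell draw its kinetic parameters from a population distribution — a
nonlinear mixed-effects (NLME) dynamical model.  The quantity of interest
is then the distribution itself: the fixed effects **b** (population mean)
and the random-effects covariance **D**, with `beta_i ~ N(b, D)` and

    dx_i/dt = g(x_i) beta_i + h(x_i),        x_i(0) known,
    y_i(t_j) = Q x_i(t_j) + eps,   Var eps_k = sigma_k^2 + tau_k^2 x_k^2.

`gmgts` implements the **gradient-matching global two-stage (GMGTS)**
estimator for such models.  Stage I estimates each cell's parameters by
regressing spline-smoothed time derivatives on the model rates — a
(feasible generalized) least-squares problem when the right-hand side is
linear in the parameters, as mass-action kinetics always are — together
with a delta-method covariance `C_i`.  For partially observed systems the
unmeasured states are reconstructed by integrating the ODE inside a short
fixed-point loop with forward sensitivities, so only a handful of
integrations per cell are ever needed.  Stage II pools `(beta_hat_i, C_i)`
by EM, deconvolving estimation noise from true population spread.  A
classical trajectory-matching first stage (the GTS baseline, multistart
nonlinear least squares) is included for accuracy and cost comparisons and
shares the same second stage.

The package is aimed at systems-biology modelers working with single-cell
trajectories (time-lapse fluorescence microscopy and similar), and ships
three fully worked study systems: a 16-species generalized Lotka–Volterra
ring, the repressilator (with a mass-action expansion that restores
linearity in the parameters), and fluorescent-protein maturation kinetics
observed only through mature fluorescence.

## A worked example

Infer the joint population distribution of the protein synthesis rate
`k_p` and maturation rate `k_m` from fluorescence-only measurements of 200
simulated cells (mRNA and dark protein are hidden states):

```python
import numpy as np
from gmgts import generate_scenario, fit_gmgts

ds = generate_scenario("fp_one_step", seed=2, overrides={"N": 200})
res = fit_gmgts(ds)

b  = res.population.b_hat
cv = np.sqrt(np.diag(res.population.D_hat)) / b
print(b.round(4), cv.round(2), f"{np.log(2)/b[1]:.1f} min half-time")
```

Output from this run:

```
[0.0254 0.0465] [0.24 0.24] 14.9 min half-time
```

The generating population had means (0.025, 0.05) min⁻¹ with a
coefficient of variation of 0.25 for both rates: the recovered means are
within 2–7% and the recovered CVs within ~5%, from measurements of a
single fluorescent species.  `np.log(2)/b[1]` converts the mean maturation
rate into the maturation half-time that microscopists usually quote.
`res.individuals` holds the per-cell estimates and covariances,
`res.convergence_fraction` the share of cells whose hidden-state loop
converged (1.0 here), and `res.n_integrations` the total ODE integrations
(about six per cell — trajectory matching needs hundreds).

The `examples/` directory has one short script per capability: full-state
Lotka–Volterra inference, hidden-state maturation inference, the
repressilator mass-action expansion, the trajectory-matching comparison,
and the Wasserstein accuracy metric.

There is also a thin command line:

```
gmgts simulate --scenario repressilator --seed 1 --outdir out/
gmgts fit      --data out/repressilator.csv --outdir out/
gmgts evaluate --data out/repressilator.csv --outdir out/
```

## Layout

- `src/gmgts/models.py` — NLME model types, simulation, observation noise
- `src/gmgts/systems.py`, `scenarios.py` — builtin systems and study designs
- `src/gmgts/smoothing.py` — penalized B-splines, GCV, noise estimation
- `src/gmgts/gls.py` — stage I, full observation (FGLS gradient matching)
- `src/gmgts/hidden.py` — stage I, hidden states (sensitivity-based fixed point)
- `src/gmgts/em.py` — stage II EM, normal and log-normal
- `src/gmgts/trajectory.py` — GTS trajectory-matching baseline
- `src/gmgts/metrics.py` — Gaussian 2-Wasserstein accuracy metric
- `src/gmgts/pipeline.py`, `io.py`, `cli.py` — end-to-end runs, file formats, CLI

`docs/methods.md` documents the model, the estimators, every tunable
default, and the known limitations.
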