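# oursense

A biomass soft sensor for aerobic fed-batch cultures.  Bioreactor operators
rarely have an online biomass probe, but every instrumented reactor measures
off-gas oxygen.  `oursense` turns the cumulative oxygen uptake rate (cOUR)
into an online estimate of biomass concentration, using only strain-level
stoichiometric parameters identified once from historical runs — no
reactor-specific model, no growth-rate observer, no neural network.

## The model

Oxygen consumption of an aerobic culture follows a Luedeking–Piret balance,

```
OUR(t) = α · X′(t) + β · X(t)
```

where `X` is biomass (g DCW/l), `α` (g O₂ / g DCW) is the specific oxygen
yield for growth, and `β` (the maintenance coefficient) covers cell upkeep
and product formation.  Integrating from inoculation gives

```
cOUR(t) = α · (X(t) − X₀) + ∫ β X dt,
```

which is the working equation of both stages:

* **Stage A (offline identification).**  `β` is modeled as a time ramp
  `β(t) = k₁ · (t − tᵢ)` activated at an induction/onset time `tᵢ` (the
  IPTG injection for *E. coli*; inferred for yeast).  Given sparse offline
  dry-cell-weight samples `X_m` and the matched `cOUR_m`, the criterion is a
  negative weighted sum of squared residuals with Monod-form per-sample
  variance `σ²_m ∝ X_m² / (1 − K_exp + K_exp X_m²)`.  The weight `K_exp ∈
  [0, 1]` interpolates between squared-percentage-error weighting (0) and
  ordinary least squares (1); 0.4 is the recommended default.  Maximizing
  the criterion in `(α, k₁)` is a 2×2 weighted linear system solved in
  closed form; `tᵢ` is found by exhaustive criterion maximization over a
  candidate grid when unknown.  The per-sample values `β(t_m)` are then
  regressed against biomass to give the strain law `β(X) = k_β₂X² + k_β₁X +
  k_β₀` and its activation threshold `X_specific` (the root of `β(X) = 0`,
  or the parabola's stationary point when no real root exists).

* **Stage B (online estimation).**  With strain parameters fixed, biomass
  follows recursively from the cOUR stream alone:
  `X_m = cOUR_m/α + X₀` below `X_specific`, and
  `X_m = (cOUR_m − Σ β(X_l)·X_l·Δt)/α + X₀` above it, the running sum using
  the previous estimate (previous-point rule, computed once per sample).

The package ships the published parameter sets for both reference strains
(`oursense.ECOLI`, `oursense.YEAST`), a synthetic fed-batch simulator used
as the test harness, and MAE/MAPE/RMSE evaluation over the two customary
accounting windows (since inoculation, since feed start).

## Worked example

Identify a strain from one synthetic two-phase run and estimate its biomass
trajectory back from the oxygen signal:

```python
from oursense import (discrete_stage_a_experiment, fit_strain,
                      estimate_trajectory, evaluate_estimation)

# synthetic fed-batch run: alpha = 1.01 g O2/g DCW, maintenance ramp
# k1 = 4e-3 activated at t_i = 10 h, hourly offline sampling for 24 h
dataset, series = discrete_stage_a_experiment(alpha=1.01, k1=4e-3, t_i=10.0)

report = fit_strain([(dataset, series)], k_exp=0.4)
p = report.strain_parameters
print(f"alpha      = {p.alpha:.4f} g O2 / g DCW")
print(f"k1         = {p.k1:.4e} 1/h^2")
print(f"t_i        = {p.t_i:.1f} h")
print(f"x_specific = {p.maintenance.x_specific:.2f} g/l (degree {p.maintenance.degree})")

trajectory = estimate_trajectory(p, series, x0=0.2)
metrics = evaluate_estimation(trajectory, dataset, feed_start=10.0)
print(f"MAE  since inoculation = {metrics.mae_since_inoculation:.3f} g/l")
print(f"MAPE since feed start  = {metrics.mape_since_feed_start:.2f} %")
```

```
alpha      = 1.0100 g O2 / g DCW
k1         = 4.0000e-03 1/h^2
t_i        = 10.0 h
x_specific = 1.71 g/l (degree 2)
MAE  since inoculation = 0.329 g/l
MAPE since feed start  = 1.91 %
```

The generating stoichiometry (`α = 1.01`, `k₁ = 4·10⁻³`, `tᵢ = 10 h`) is
recovered exactly from noise-free data; the small trajectory errors come
from re-expressing the time-ramp maintenance as a biomass polynomial on the
coarse hourly grid.  Both stages are also available as scikit-learn style
estimators (`StoichiometryIdentifier().fit(experiments)`,
`OnlineBiomassEstimator(strain_parameters=..., x0=...).predict(series)`).

The same pipeline is scriptable from the shell:

```sh
oursense simulate --out-dir run/ --no-noise --beta-mode time
oursense fit --our run/our.csv --dcw run/dcw.csv --x0 0.2 --out params.json
oursense estimate --params params.json --signal run/our.csv --our --x0 0.2 --out traj.csv
oursense evaluate --trajectory traj.csv --dcw run/dcw.csv --feed-start 10 --out report.json
```

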