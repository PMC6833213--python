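# Methods

## Model and assumptions

The sensor rests on a Luedeking–Piret balance for oxygen: the uptake rate is
a growth term plus a maintenance term, `OUR = α·X′ + β·X`.  Working with the
cumulative signal cOUR rather than OUR filters sensor noise (integration is
a low-pass operation) and correlates directly with accumulated biomass.  The
model assumes

* `α` is constant for a strain across reactors, feeds and scales;
* maintenance-plus-product consumption `β` is negligible until an activation
  event (induction, or biomass passing a strain threshold), then grows
  smoothly — linearly in time during identification, polynomially in biomass
  for online use;
* the offline dry-cell-weight samples are the ground truth biomass, and the
  cOUR measurement error per sample has variance proportional to
  `X² / (1 − K_exp + K_exp·X²)` (Monod-form in `X²`).

Units: biomass in g DCW/l, OUR in g O₂ l⁻¹ h⁻¹, cOUR in g O₂/l, `α`
dimensionless (g O₂ per g DCW), `β` in h⁻¹ scaled by the same mass ratio,
time in hours with `t = 0` at inoculation.  These conventions are
assumptions of the package; the published `α ≈ 1` values are consistent
with them.

## Discretization

All integrals are right-endpoint rectangle sums:
`c[m] = c[m−1] + f(t_m)·(t_m − t_{m−1})`.  This mirrors the estimator
equations exactly rather than using a higher-order quadrature, because
stage A's closed form and stage B's recursion are derived for this rule;
consistency matters more than order here.  The scheme is first-order: the
test suite verifies that the stage-B trajectory error decays ~10× when the
online grid is refined from 10 min to 1 min.  One-minute sampling is the
expected online resolution; any monotone grid is accepted.

## Stage A: identification

With `M_m = Σ_{l ≤ m, t_l > t_i} (t_l − t_i)·X_l·Δt_l` the discrete model is
`cOUR_m = α(X_m − X₀) + k₁·M_m`.  Maximizing the negative weighted residual
sum is weighted linear least squares; the normal equations form a 2×2 system
solved in closed form, with weights `w_m = (K_exp X_m² + 1 − K_exp)/X_m²`.
Numerical and structural choices:

* **Maintenance sum indexing.**  Only offline samples strictly after `t_i`
  contribute to `M_m`; terms at or before the activation time would carry
  negative `(t_l − t_i)` factors, i.e. unphysical negative maintenance.
* **Variance proportionality constant.**  The Monod-form variance is defined
  up to a positive scalar; it cancels in the normal equations and is fixed
  to 1.
* **`t_i` search.**  When the activation time is unknown (yeast) it is found
  by exhaustive search over a candidate grid (default: the offline sample
  times), scoring each candidate with the criterion at its own closed-form
  optimum.  Exhaustive search is exact on the grid and cheap at the ≤ ~30
  offline samples a fed-batch run produces; ties break toward the earliest
  candidate, which activates maintenance conservatively early.  If no sample
  follows the chosen `t_i`, the slope is unidentifiable; the fit returns
  `k₁ = 0` with a data-quality warning.
* **Degenerate systems.**  A relative determinant below 10⁻¹² of `B·F`
  raises a degenerate-fit error naming the collinearity.
* **Pooling across experiments.**  Each run is solved separately; the strain
  `α` is the mean weighted by each run's growth-regressor precision (the `B`
  sum), `k₁` analogously by the maintenance precision (`F`), and `t_i` is
  the per-run median.  The pooling rule is this package's choice; with
  identical replicates it reduces to the single-run fit (tested).
* **β(X) regression.**  The per-sample values `β(t_m) = k₁(t_m − t_i)` are
  regressed on `X_m` by ordinary least squares at degree 1 or 2.  Degree 2
  is the default; it is downgraded to degree 1 when the fitted parabola is
  decreasing at the top of the observed biomass range, and maintenance is
  disabled entirely (with a warning) when no usable threshold exists — both
  situations arise under heavy noise.
* **`X_specific`.**  Degree 1: the root `−k_β0/k_β1`.  Degree 2: the largest
  real root; when the discriminant is negative the parabola never crosses
  zero and the stationary point `−k_β1/(2k_β2)` is used instead and flagged.
  The published *E. coli* coefficients are exactly this case: their
  stationary point reproduces the published 20.6 g/l threshold.
* **Negative-β clamp.**  Both parameterizations clamp at zero everywhere,
  not only before activation, so a fitted law can never credit oxygen back.

`K_exp` defaults to 0.4.  At 1 the fit is ordinary least squares, at 0 it is
1/X²-weighted; the weight is linear in `K_exp` between the two, and both
limits are verified against independently computed least-squares solutions.

## Stage B: online estimation

The recursion uses the previous biomass estimate for the maintenance accrual
over each interval and computes each point once (no inner iteration).  The
regime switch at `X_specific` is latched — once the estimate has crossed the
threshold the correction stays on — to avoid chattering when the trajectory
hovers near it.  Estimates are floored at zero; cOUR drops larger than
10⁻⁶ g/l (sensor glitches) produce a warning but the stream value is used
as-is, and per-point warnings are aggregated to one summary per trajectory.
The initial biomass can be given directly or as optical density at
0.4 g/l per optical unit.

## Synthetic data

The simulator emulates a two-phase fed-batch: constant specific growth rate
`μ_max` until induction, then `μ(t) = μ_max·e^{−d(t−t_ind)}`, for which the
biomass trajectory has a closed form (no integration error in the truth).
Defaults describe a recombinant *E. coli* run: `x₀ = 0.2 g/l`,
`μ_max = 0.35 h⁻¹`, induction at 10 h, deceleration `d = 0.2 h⁻¹`, 24 h
total, `α = 1.01`, the published parabolic maintenance law, 1-min online
grid, hourly offline samples, 2% multiplicative cOUR noise and 5% DCW noise.
The run crosses `X_specific = 20.6 g/l` at ≈15 h and ends near 34 g/l, a
realistic high-cell-density trajectory.

Two deliberate generation choices:

* The dense OUR signal is built from backward differences of the exact
  biomass, so the right-endpoint cumulative rule telescopes and
  `cOUR = α(X − X₀)` holds exactly on the grid when `β ≡ 0`; the maintenance
  term keeps its O(Δt) character, which is what the convergence tests probe.
* `discrete_stage_a_experiment` generates offline cOUR observations directly
  from the discrete identification model, so the stage-A equations hold with
  zero residual and recovery of `(α, k₁, t_i)` to ≤ 10⁻⁶ relative is a
  meaningful correctness check rather than a discretization lottery.  Data
  from the continuous simulator instead carries an O(offline-interval)
  Riemann bias (~1% in `α` at hourly sampling), which is the realistic
  situation.

Noise is multiplicative Gaussian (optionally Monod-form scaled), unbiased,
and fully seeded.  What the simulator does **not** emulate: substrate and
feed mass balances, dissolved-oxygen dynamics, CO₂ signals, broth-volume
changes, sampling dead volumes, or metabolic shifts (overflow metabolism,
diauxie).  Passing tests therefore demonstrate correctness of the estimator
arithmetic and its noise robustness under the model's own assumptions, not
validity of the stoichiometric model for any particular organism.

## Evaluation

MAE, MAPE and RMSE are computed at the offline sample times only (offline
DCW is the reference), matching each sample to the nearest trajectory point
within half the online sampling interval, over two windows: since
inoculation and since feed start.  Zero observations are a hard error for
MAPE rather than being dropped, to keep window comparisons unbiased.

## Problem sizes

The shipped tests and the acceptance script use 24-h cultures at 1-min
online resolution (1441 points), hourly offline sampling (24 samples),
20 noise seeds for the stage-A study, 10 for stage B, and 50 random
instances for the brute-force solver cross-check — sizes chosen to mirror a
realistic fed-batch campaign while keeping a full run to well under a
minute.

## Known limitations

* `α` and the maintenance law are assumed strain-constant; feed-strategy or
  product-load effects fold into `β` unmodeled.
* The confidence of identified parameters is not quantified (no standard
  errors or intervals are produced).
* The online estimator has no measurement-update step; it is open-loop in
  biomass and inherits any bias in cOUR (e.g. a mis-calibrated gas
  analyzer) scaled by 1/α.
* Computing OUR from raw off-gas mole fractions and gas flow is out of
  scope; the package starts from an OUR or cOUR signal.
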