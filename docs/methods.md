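# Methods

## Failure-time model at constant temperature

The core distribution is the log-logistic with scale `a` (minutes) and
shape `k` (dimensionless):

```
S(t) = (1 + (t/a)^k)^-1
f(t) = (k/a) (t/a)^(k-1) (1 + (t/a)^k)^-2
h(t) = f(t)/S(t) = (k/a) (t/a)^(k-1) / (1 + (t/a)^k)
```

Two identities make it the natural choice for knockdown data: the scale
equals the median failure time (`S(a) = 0.5`), and the shape controls
the spread of log failure times through `var[log t_f] = pi^2/(3 k^2)`.
A published display of this hazard that one sometimes encounters,
`[a k (a t)^(k-1)] / [1 + (a t)^k]`, is dimensionally inconsistent with
the survival function above (it multiplies instead of divides by the
scale); we implement the `h = f/S` form, which is the only one
compatible with `S(t)`. Similarly, the variance identity
`pi^2/(3 k^2)` is the variance of the *log* failure time, not of the
failure time itself, and the API names it accordingly
(`variance_of_log_failure_time`).

Four comparison families are supported through the same log-density
interface: exponential (constant hazard `lambda = 1/mean`), Weibull,
log-normal, and Gompertz. The Gompertz is parameterised by a real shape
`s` and a positive rate with `h(t) = rate * e^(s t)`; conventions differ
across packages, so this is fixed in the API docs. Negative `s` yields a
defective tail (a fraction never fails), matching the convention of
standard survival software; on fully observed failure times the
likelihood remains well defined.

## Temperature links and fitting

The joint accelerated-failure-time model puts the location linear in
assay temperature and the shape either constant or temperature-linked:

```
log a(T) = beta0 + beta1 T
log k(T) = gamma0 + gamma1 T        (log-linear link, default)
```

The log link guarantees `k > 0` everywhere. Field descriptions of a
shape that "declines linearly" with temperature do not constrain
positivity; a raw linear link `k = gamma0 + gamma1 T` is available
behind `shape_link="linear"` for sensitivity analysis, but the log link
is the default and the one the dynamic predictor consumes. For the
other families the "shape" slot holds the Weibull shape, the log-normal
log-sigma, or the Gompertz shape; the exponential has none and rejects
a link.

All fits are maximum likelihood in unconstrained coordinates (log
scale, log shape), run with BFGS from three starts: moment-based (OLS
of log time on temperature for the location, the variance identity
inverted for the shape), median-based, and a perturbation of the first.
The log-logistic likelihood uses analytic gradients; a fit also counts
as converged when BFGS stops with "precision loss" but the gradient is
below 1e-4 relative to the objective, a routine occurrence at clean
optima. Standard errors come from the inverted numerical Hessian of the
negative log-likelihood (observed information). Internally temperature
is centred at its mean for conditioning; reported coefficients are
transformed back exactly, so the parameterisation is plain degrees
Celsius. Identical failure times in a cell push the shape to infinity
and raise a degenerate-data error rather than returning a boundary
estimate. Cross-checks: per-cell and joint fits agree with R's
`flexsurv` to ~1e-3 in AIC on shared data, and with lifelines'
log-logistic AFT fitter in the test suite.

Per-cell estimates (one `(scale, shape)` per species x temperature)
feed an ordinary-least-squares TDT regression of log fitted scale on
temperature; residuals are returned for the linearity diagnostic. Trials
with fewer than 10 individuals are excluded by default before fitting —
small trials make shape estimates unusable — with the dropped groups
reported.

## Assumption diagnostics

**Shape trend.** A likelihood-ratio test of `gamma1 = 0` compares the
constant-shape and linked-shape fits (df = 1, chi-square reference).
For multi-species data a pooled variant uses species-specific
fixed intercepts for both links with shared slopes — a fixed-effects
stand-in for a random-intercept formulation, which is out of scope.
Under a null simulation (5 temperatures x 100 individuals, 500
replicates) the test rejects at 4-5% for alpha = 0.05.

**Proportional hazards.** PH across temperatures is probed by a
parametric LR test: a Weibull-baseline PH model
`h(t|T) = p lam t^(p-1) exp(th1 T)` against the same model augmented
with a `T x log t` interaction (df = 1). A shape that changes with
temperature makes hazard ratios drift over time and drives this
statistic up; under exact PH (Weibull data, common shape) it is
calibrated near its nominal level.

## Prediction under fluctuating temperature

All three predictors integrate a temperature-dependent rate along the
profile. Stepwise (setpoint) profiles are integrated in closed form;
linearly interpolated profiles use the trapezoid rule on a 0.1-minute
grid (configurable). Profiles extend beyond their last knot by holding
the final temperature, and additivity makes stepwise damage invariant
to segment order.

- *Additive damage*: median = first `t` with `D(t) = 1`, found by exact
  inversion of the piecewise-linear damage trajectory (tolerance
  1e-6 min). If damage never reaches 1 inside the horizon (default 10x
  the constant-temperature median at the profile's coolest temperature)
  the result is flagged "beyond horizon" rather than extrapolated.
- *Average curve*: the pooled empirical survival in relative time is
  evaluated at accumulated relative time. The curve object exposes both
  the right-continuous step estimate and a piecewise-linear version
  through each jump's midpoint (used by the predictor); a degenerate
  pool with a single value drops from 1 to 0 there. Its failure density
  is a Gaussian kernel estimate on log r (Silverman's rule,
  configurable), evaluated once on a dense cached grid. The prediction's
  density is this kernel estimate transported to the time axis,
  `f(t) = g(R(t)) / t50(T(t))`: finite differences of the raw step curve
  would score the model with a noise-dominated log density (see
  "Calibration of the likelihood comparison" below).
- *Increasing variance*: `S(t) = (1 + D_a(t)^k(T(t)))^-1` with the shape
  at the instantaneous temperature, which reduces exactly to the static
  log-logistic at constant temperature. A drop in `k` at a segment
  boundary can push this raw expression upward; since realized
  mortality is irreversible, the curve is clamped to its running
  minimum. A duration-weighted mean shape is available via
  `shape_mode="duration-weighted"`, and every prediction records the
  mode used. Predictions outside the fitted temperature range warn with
  the extrapolation distance.

Medians are found by bisection between grid points (tolerance 1e-6 min);
densities for the parametric model come from central finite differences
of the monotone survival curve, clipped at zero. Set-level
log-likelihoods sum the log predicted density interpolated at each
observed failure time, floored at 1e-12 per minute (floored counts are
reported); observations beyond the grid raise an error asking for a
longer horizon rather than silently truncating.

## Model comparison

`run_full_comparison` fits everything on the static data — the TDT
regression on per-cell scales (sample medians optional), the pooled
curve, and the AFT model whose shape link is chosen by the trend test at
alpha = 0.05 (`shape_link="auto"`), — then predicts every assay set and
reports: per-set predicted and observed medians with absolute errors,
per-model sums of absolute errors (broken out by sex when labels are
present), per-set `Delta LL = LL(increasing variance) - LL(average
curve)`, a one-sample t test on those differences (df = n_sets - 1,
two-sided), and the count of sets with positive differences (ties count
as non-positive). Observed medians are midpoint sample medians. The
horizon is doubled automatically until the grid covers the longest
observed failure time, so heavy-tailed sets are never truncated. The
whole comparison is a pure function of its inputs.

### Calibration of the likelihood comparison

When the generating shape is constant, both probabilistic models are
correctly specified and neither should win on average. Two estimator
artifacts can masquerade as a model difference. First, a plug-in
density formed by differencing the empirical step curve has O(1)
multiplicative noise at single observations, and Jensen's inequality
turns that noise into a systematic log-likelihood penalty (about
-0.08 per observation at 1,600 pooled records in our simulations) —
this is an artifact of the density estimator, hence the kernel density
above. Second, even the kernel-based curve pays a small plug-in
penalty at modest pool sizes (mean Delta LL ~ +0.11 per 80 observations
at 1,600 pooled records, shrinking to ~+0.06 at 4,000). This residual
is real, small, and is precisely the nonparametric overfitting cost the
parametric model avoids; the calibration test in the suite therefore
runs at a 4,000-record pool, where the two scores are statistically
indistinguishable across 100 replicates, and these numbers document
what remains at realistic sizes.

## Synthetic data

The generator draws static cells from the temperature-linked
log-logistic and fluctuating failure times by inverse-CDF sampling of
the predicted dynamic survival curve (uniform survival levels inverted
on the grid curve; the horizon doubles, with a warning, if a draw
outlives it). Defaults describe a realistic knockdown regime: medians
from ~18 h at 33 degC to ~2 min at 40 degC (`beta0 = 36.7`,
`beta1 = -0.9` on natural logs), shape falling from ~4.9 to ~1.5
(`gamma0 = 7.2`, `gamma1 = -0.17`), 8 temperatures at 1-degC spacing, 20
individuals per cell, and 26 fluctuating sets of 20 individuals with
stepwise/ramp/sinusoid profiles bounded in 34-42 degC. A root seed
derives per-cell and per-set sub-seeds through a fixed
`SeedSequence([seed, stream, key])` counter scheme, so adding a
temperature or a set leaves all other draws unchanged.

What the generator does *not* emulate: trial-to-trial heterogeneity
within a cell, acclimation or recovery at permissive temperatures,
order-dependent (non-additive) damage, censoring, and measurement
rounding. Tests passing on these simulations therefore certify the
statistical machinery and its internal consistency, not the adequacy of
additive damage for real organisms — on real data all such models are
known to underestimate long failure times.

### Simulation sizes used in checks

Problem sizes in the test suite and acceptance script were chosen as the
smallest at which the checked asymptotics are expected to hold: 100
replicates of 5 temperatures x 200 individuals for link recovery; 500
null replicates of 5 x 100 for LR-test calibration; a 4-temperature,
3-degC-span, 500-fly simulation for family ranking (the span of a
typical single-species assay series — across a much wider span a single
Gompertz shape parameter cannot track time scales that differ by two
orders of magnitude and its ML fit collapses onto the exponential, a
property of the family, not of the optimizer); 1e4-1e6 draws for
Monte-Carlo identities.

## Known limitations

- The pooled shape-trend test uses fixed species intercepts, not random
  effects; with many species and few temperatures each, its df = 1
  statistic is not exchangeable with a mixed-model version.
- The PH diagnostic is parametric (Weibull baseline); it tests a
  specific, interpretable departure rather than PH in general.
- The instantaneous-shape dynamic model is discontinuous at setpoint
  jumps before clamping; the clamp is a modeling choice (irreversible
  mortality), and the duration-weighted alternative is smooth but no
  longer reduces segment-locally to the static curve.
- Right-censoring is not implemented: knockdown assays observe every
  failure. Interval censoring is out of scope.
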