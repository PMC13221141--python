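# tdtsurv

Thermal-death-time (TDT) survival modeling for ectotherm heat-tolerance
data: fit parametric failure-time models to constant-temperature
knockdown assays and predict median failure times and full survival
curves under fluctuating stressful temperatures.

## The problem

At stressful temperatures, the time to failure (knockdown, heat coma,
death) of insects and other ectotherms declines exponentially with
temperature, giving the classic TDT line

```
log t_f = beta0 + beta1 * T          (beta1 < 0, ~ -0.9 per degC for Drosophila)
```

Predicting survival under *fluctuating* temperature from constant-
temperature assays requires extra assumptions, and three model families
make different ones:

1. **Additive damage (deterministic).** Injury accrues at rate
   1/t50(T); the predicted median failure time is the first `t` with
   `D(t) = ∫ du / t50(T(u)) = 1`. No survival curve.
2. **Average survival curve (nonparametric).** All observed failure
   times are rescaled to relative time `r = t_f / t50(T)` and pooled;
   a single curve `C(r)` is applied to accumulated relative time:
   `S(t) = C(R(t))`. This assumes the *shape* of the survival curve
   does not change with temperature.
3. **Increasing-variance log-logistic (parametric).** At constant T,
   `S(t) = (1 + (t/a)^k)^-1` with `log a(T) = beta0 + beta1 T` and
   `log k(T) = gamma0 + gamma1 T`. The scale `a` equals the median
   failure time and `var[log t_f] = pi^2 / (3 k^2)`, so `gamma1 < 0`
   means the spread of failure times grows with temperature. Under a
   profile, scaled damage `D_a(t) = ∫ du / a(T(u))` replaces `t/a` and
   the shape is evaluated at the instantaneous temperature.

The package fits all of these (maximum likelihood, with AIC comparison
across log-logistic, Weibull, log-normal, Gompertz and exponential
families), provides likelihood-ratio diagnostics for a shape-temperature
trend and for proportional-hazards violations, scores the three
predictors against observed fluctuating assays (sum of absolute median
errors, per-set log-likelihood differences, paired t test), and includes
a synthetic-data generator so the whole pipeline is testable offline.

Intended users: thermal ecologists and biostatisticians working with
static knockdown series (one row per individual: species, temperature,
failure time in minutes) and chamber experiments with programmed
temperature profiles.

## Worked example

Simulate a static series plus eight fluctuating assay sets, fit, and
compare the three predictors:

```bash
tdtsurv simulate --seed 11 --n-per-cell 25 --n-sets 8 --out-dir demo/sim
tdtsurv fit     --input demo/sim/static.csv --out-dir demo/fit
tdtsurv compare --static demo/sim/static.csv \
                --profiles demo/sim/profiles.csv \
                --observed demo/sim/observed.csv --out-dir demo/cmp
cat demo/cmp/summary.txt
```

prints

```
model comparison summary
----------------------------------------
SAE increasing_variance: 8.6 min
SAE jorgensen: 13.8 min
SAE rezende: 17.1 min
paired t on Delta-LL: t=1.9311, df=7, p=0.09477
increasing variance better in 8 of 8 sets
```

The SAE lines are each model's summed absolute error in predicted median
failure time over the eight sets (minutes); the paired t test acts on
the per-set log-likelihood difference between the increasing-variance
and average-curve models (positive favours increasing variance), and the
last line counts the sets in which the increasing-variance model fits
the observed failure-time distribution better. Because these sets were
generated from an increasing-variance model, it wins in all eight. The
fit summary (`demo/fit/fit_summary.csv`) recovers the generator's TDT
slope: `tdt_slope = -0.976` against a true value of -0.9, with r² 0.99.

The same workflow runs from Python via `tdtsurv.run_full_comparison`,
`tdtsurv.fit_aft_model`, `tdtsurv.predict_survival_increasing_variance`
and friends; see `docs/methods.md` for the model details and numerical
choices.

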