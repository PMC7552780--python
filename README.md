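# lactofit

Individual lactation-curve analysis for dairy-goat milk components.

Milk recording schemes produce a handful of monthly test-day controls per
lactation: daily yield plus protein, fat, dry matter, lactose (%) and
somatic cell count (cells/mL).  Breeding and management decisions — and
genetic studies forced onto small genotyped samples — need the *individual*
trajectory of each component over days in milk (DIM), not just herd
averages.  `lactofit` is a toolkit for exactly that workflow:

* **standardize** whole-lactation yields: real production
  `RP = d1·P1 + 30·ΣPᵢ + [d2 − 30(n−2)]·Pn`, normalized production (interval
  means), and the 210-day trapezoidal accumulated yield MP210;
* **fit** a catalogue of 49 linear and nonlinear curves
  y = f(t; b0..b4) — Wood `b0·t^b1·e^(−b2·t)`, Wilmink
  `b0 + b1·e^(−b3·t) + b2·t`, the five-parameter Ali-Schaeffer regression
  `b0 + b1(t/210) + b2(t/210)² + b3·ln(210/t) + b4·ln²(210/t)`, the
  parabolic yield-density `1/(b0 + b1·t + b2·t²)`, splines, Legendre
  polynomials, growth curves … — per goat × component, by
  Levenberg-Marquardt with analytic Jacobians and a relative
  error-sum-of-squares convergence criterion of 1e-8;
* **select** models with adjusted R² (± SD across goats), the
  adj-R²/R² overfit ratio, AIC / AICc / BIC, MSPE, leave-one-out
  cross-validated MMSE, and per-model percentages of successfully fitted
  curves;
* **diagnose** residuals: Shapiro-Francia normality, Levene
  homoscedasticity, Durbin-Watson on the day-mean residual series, sign
  runs test;
* **shape**: peak (t*, y*) with closed forms where they exist (Wood
  t* = b1/b2, …) and persistency under three definitions (post-peak rate,
  halfway relative rate y′/y, instantaneous rate), with a
  change-per-control fallback for monotone curves;
* **compare** model-complexity classes (2-5 regressors) with
  Jeffreys-Zellner-Siow mixture-of-g-prior Bayes factors (one-way ANOVA
  and Bayesian Pearson correlations between curve parameters), posterior
  class means and 95% credible intervals;
* **simulate** seeded synthetic herds that reproduce recording-scheme
  structure (first control 21.2 ± 13.7 d, 4.8 ± 2.9 controls/lactation,
  210-240 d lactations) and per-component coefficients of variation
  (14.1 / 21.7 / 10.0 / 6.6 / 148.7 %), with ground-truth sidecars for
  recovery testing.

The per-series fitter is a scikit-learn estimator (`CurveRegressor`), so it
composes with sklearn model selection; everything else is plain functions
over pandas tables.  A `lactofit` CLI chains the stages end to end.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from lactofit import (HerdConfig, generate_herd, read_testday_table,
                      build_series, sweep, rank_models, find_peak, persistency)

generate_herd(HerdConfig(n_goats=20, generating_model="ALISCH", seed=42),
              out_csv="herd.csv")
table = read_testday_table("herd.csv")
series = build_series(table, "protein")          # one pooled series per goat
result = sweep(series, ["ALISCH", "WOOD", "WILMINK", "QUADRT", "SIMLIN"])
print(rank_models(result)[["mean_adj_r2", "sd_adj_r2", "percent_fitted",
                           "mean_aicc", "rank"]].round(3))
```

```
         mean_adj_r2  sd_adj_r2  percent_fitted  mean_aicc  rank
model
ALISCH         0.604      0.449            90.0     -7.960     1
WILMINK        0.562      0.302            70.0     -8.625     2
WOOD           0.492      0.269           100.0     -7.673     3
QUADRT         0.344      0.438           100.0     -5.270     4
SIMLIN         0.245      0.444           100.0     -6.097     5
```

The herd was generated from Ali-Schaeffer curves with protein-level noise
(CV 14.1%), and the ranking recovers that: ALISCH captures the most
between-day variability per goat (mean adjusted R² 0.604) even after its
five-parameter penalty, while simpler curves trail in order of
flexibility.  `percent_fitted` is the share of goats whose series
converged for that model — short series (n ≤ k) count as failures.

Shape parameters of a fitted Wood curve `b = (3, 0.2, 0.01)`:

```python
t_pk, y_pk = find_peak("WOOD", [3, 0.2, 0.01])     # day 20.0, value 4.4717
persistency("WOOD", [3, 0.2, 0.01], t_pk,
            method="halfway_relative_rate")         # -0.008261 per day
```

The curve peaks at day 20 (b1/b2) and declines at 0.83%/day at the point
halfway between peak and day 210.

The same pipeline from the shell:

```bash
lactofit simulate --seed 42 --n-goats 20 --out herd.csv
lactofit fit --input herd.csv --component protein \
             --models ALISCH,WOOD,PARYLDENS --out fits.csv
lactofit run --seed 42 --out-dir run/       # full bundle: CSVs + plots
lactofit models list                        # the 49-model catalogue
```

## Layout

```
src/lactofit/
  io.py          test-day tables, series, RP/NP/MP210
  catalogue.py   the 49-model registry (equations, gradients, initializers)
  fitting.py     CurveRegressor, fit_series, sweep
  selection.py   adj R², AIC/AICc/BIC, MSPE, LOOCV-MMSE, ranking
  diagnostics.py Shapiro-Francia, Levene, Durbin-Watson, runs test
  shape.py       peak, persistency, change-per-event
  bayes.py       JZS ANOVA + Pearson Bayes factors, credible intervals
  simulate.py    synthetic herds, mastitis spikes
  pipeline.py    end-to-end driver (deterministic artifact bundle)
  cli.py         `lactofit` command group
docs/methods.md  model and algorithm documentation
```
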