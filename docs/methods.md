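# Methods

`lactofit` analyses the evolution of milk composition (protein %, fat %,
dry matter %, lactose %, somatic cell count) over a goat's lactation, one
animal at a time.  This note documents the models, the numerical choices,
and what the synthetic-herd tests do and do not establish.

## Data model and yield standardization

A test-day record is one official monthly control: goat, lactation number,
kidding date, control date, daily milk yield (kg) and the five component
measurements.  Days in milk (DIM) is the whole-day difference between
control and kidding date; the day of kidding is day 0 and is excluded from
series (log- and power-containing models need t >= 1).  The fitting unit is
a component series — ordered (DIM, value) pairs for one goat x component.
By default all lactations of a goat are pooled into one series (lactation
order is routinely found not to shift composition means); `per_lactation=True`
fits each lactation separately.

Whole-lactation milk yield is summarized three ways, with d1 the days from
kidding to first control and d2 the days between the last two controls:

* **RP** (real production): `d1*P1 + 30 * sum(P_i, i=2..n-1) + [d2 - 30(n-2)] * Pn`.
  The 30-day interior weight presumes roughly monthly controls; a warning
  fires when spacing departs from monthly by more than 10 days, and when
  the residual last-interval bracket becomes negative (value not clamped).
* **NP** (normalized production): same skeleton with interval means,
  `d1*P1 + 30 * sum((P_i+P_{i+1})/2, i=1..n-2) + [d2 - 30(n-2)] * (P_{n-1}+Pn)/2`.
* **MP210**: the exact integral of the piecewise-linear interpolant of
  (DIM, yield) from the first control to day 210, i.e. a trapezoidal sum
  with the final partial interval clipped by linear interpolation at day
  210 (disable with `truncate_at=None`).  No truncation rule is standard
  for the trapezoidal summary; interpolation is the only choice consistent
  with treating the interpolant as the yield curve.

All three are linear in the yields and agree exactly on 30-day grids with
constant yield; both facts are asserted as properties in the test suite.

## The model catalogue

Forty-nine registered curves, from the straight line up to five-parameter
forms (Ali-Schaeffer polynomial-log regression, cubic spline with one
knot).  Each entry stores a sympy equation in `t` and `b0..b4`; pointwise
values, parameter gradients and time derivatives are generated
symbolically and lambdified once per model, so Levenberg-Marquardt always
receives an analytic Jacobian and persistency always has an analytic
derivative.  Registry conventions:

* The Ali-Schaeffer regressors use a fixed standardized lactation length
  DIM = 210 d (rebindable per model via `get_model("ALISCH", DIM=...)`).
* Spline knots default to day 105, the midpoint of [1, 210]; a per-series
  knot can be bound the same way.  Knot-placement strategies beyond a
  single fixed knot are deliberately out of scope.
* The third-order Legendre model maps [1, 210] to [-1, 1] and uses
  unnormalized Legendre polynomials.
* The Wilmink decay rate is a free fourth parameter bounded to
  [1e-4, 1]; fixing it to the classical 0.05 is a one-line rebind in user
  code since the registry is declarative.
* `regressor_count` (the 2-5 "elements" grouping used in the complexity
  comparison) equals the free-parameter count; no model in this registry
  carries fixed constants that would separate the two.

Where the historical sources print only a model name, the closest
canonical literature parameterization was adopted (e.g. Dijkstra's
mechanistic exponential, the Shinozaki-Kira reciprocal line for the
yield-density slot, the Papajcsik-Bodero t-exponential / log-exponential /
arctangent forms, a generalized biexponential).  The registry is
data-driven, so replacing any single equation is a local edit.

### Initializers

42 of the 49 models register a deterministic data-driven initializer:

* linear-in-parameter models solve one least-squares problem (exact on
  noise-free data);
* linearizable models solve the transformed problem exactly — log-linear
  (Wood, Dhanoa, power, Brody, Schumacher, Gaussian, parabolic
  exponential, cubic exponential), reciprocal (yield-density family,
  Nelder, Michaelis-Menten, rational-cubic cross-multiplication);
* stiff models (Wilmink, Gompertz, logistic, von Bertalanffy,
  Mitscherlich, Cobby-Le Du, Dijkstra, biexponential rise forms) scan a
  coarse deterministic grid over the nonlinear rate and solve the
  conditionally linear part.

The remaining seven (Richards, Morgan-Mercer-Flodin, Rook, modified
Weibull, arctangent-exponential, generalized biexponential, the
rise-times-decline four-parameter form) start from a level-scaled typical
vector.  These are exactly the shapes that converge poorly on short noisy
series in field reports; their lower fitted percentages in the sweep are
expected behaviour, not defects.

## Fitting protocol

`CurveRegressor` (a scikit-learn estimator; `fit_series` wraps it)
minimizes unweighted residual sums of squares with Levenberg-Marquardt
(scipy's MINPACK driver, analytic Jacobian).  Convergence is declared when
the relative change in the error sum of squares between successive
iterations falls below `tol` (default 1e-8); the relative form keeps the
criterion meaningful from lactose (~5) to somatic cell counts (~1e6).
`max_iter` defaults to 200 — cold starts need headroom even though
well-initialized fits typically converge in a handful of iterations.
Series with n <= k points, solver failures and non-finite excursions are
recorded as non-converged with a reason; the sweep reports per-model
percentages of successfully fitted curves.  Optional seeded multi-start
jitter (`n_restarts`) is off by default.

Fit results are memoized on (series bytes, model, settings).  This makes
the pipeline exactly what it claims to be — a pure function of input
bytes, config and seed — and sidesteps a real numerical nuisance: on
nearly non-identifiable fits (e.g. a three-parameter inverse parabola on a
noisy SCC series) the LM endpoint wanders along a flat ridge under
last-bit floating-point jitter, which would otherwise break byte-identical
reruns.

## Selection criteria

Per converged fit: R^2 = 1 - RSS/TSS; adjusted
R^2 = 1 - (1-R^2)(n-1)/(n-k-1) with k the number of curve parameters
(reported as-is, including negative values); overfit ratio adj R^2 / R^2
flagged in [0, 0.4]; Gaussian least-squares information criteria
`AIC = n ln(RSS/n) + 2k`, `AICc = AIC + 2k(k+1)/(n-k-1)`,
`BIC = n ln(RSS/n) + k ln n` — the constant "+1" for the residual
variance is omitted in k consistently, so model comparisons are
unaffected; MSPE = RSS/n (in-sample; emitted alongside, and distinct
from, the cross-validated MMSE); MMSE = leave-one-out mean squared
prediction error with each fold refit warm-started from the full-data
solution (deterministic; failed folds dropped and counted).

`rank_models` aggregates over converged individuals only and ranks by
mean adjusted R^2 (the criterion that actually separates models in
individual-curve studies), ties broken by fewer parameters, then lower
BIC.

## Residual diagnostics

* **Durbin-Watson** on the day-mean residual series (residuals averaged
  per DIM across goats, giving one ordered series; per-series DW is also
  available).  Values below 2 indicate positive first-order
  autocorrelation.
* **Runs test** on residual signs, normal approximation, zeros dropped.
* **Shapiro-Francia** W': squared correlation between order statistics
  and expected normal scores at Blom plotting positions (alpha = 3/8),
  p-value from Royston's (1993) log-normal approximation of 1 - W'
  (valid for 5 <= n <= 5000).
* **Levene** on absolute deviations from group means (the common
  statistical-package default; `center="median"` gives Brown-Forsythe).

## Curve shape parameters

The peak is the interior maximum of the fitted curve on the observed DIM
range intersected with [1, 210].  Closed forms are registered where they
exist (Wood t* = b1/b2; inverse parabola and quadratic t* = -b1/(2 b2);
Gaussian t* = b1; t-exponential t* = 1/b1; Sikka t* = b1/(2 b2)); other
models are maximized numerically — coarse grid bracket, then Brent
root-finding on the analytic time derivative (value-based refinement
cannot localize flat maxima below the floating-point noise floor).
Monotone curves return no peak and fall back to the net fitted change per
control event: (fitted value at last observed DIM minus at first) /
(controls - 1) — a reporting convention, labelled as such in output.

Persistency has three operational definitions: `post_peak_rate`
(average decline between peak and day 210), `halfway_relative_rate`
(y'/y at the midpoint between peak and end — invariant to rescaling the
component), and `instantaneous_rate` at a caller-chosen day.  Derivatives
are symbolic; a central-difference fallback (h = 1e-4 d) covers curves
supplied as bare callables.

## Bayesian comparison

One-way ANOVA under the Jeffreys-Zellner-Siow mixture of g-priors:
standardized group effects get N(0, g I) on the orthonormalized
sum-to-zero design, g ~ InverseGamma(1/2, scale^2/2) (a Cauchy effect
marginal), and (mu, sigma^2) the location-scale Jeffreys prior — which
makes BF10 exactly invariant to shifting/rescaling the response.  BF10 is
a one-dimensional adaptive quadrature over g (substituted to (0,1)), with
the N x N algebra reduced by the Woodbury identity.  The default prior
scale is sqrt(2)/2, the conventional "medium effect" for ANOVA effects;
the constant is exposed because reported SPSS-era values of this scale
are internally inconsistent and could not be reproduced.  Posterior class
means and equal-tail 95% credible intervals come from seeded Monte Carlo
(g from its gridded marginal, then conjugate normal-inverse-gamma
conditionals; 10,000 draws by default).  A comparison is "flagged" when
BF10 > 3 (moderate evidence); evidence labels follow the
Jeffreys / Lee-Wagenmakers bands.

The Pearson-correlation posterior is built on a rho grid from the exact
sampling density of the observed correlation (Gaussian 2F1 form) with the
JZS-consistent stretched-beta prior (kappa = 1, i.e. uniform on [-1, 1]);
BF10 compares the prior-averaged marginal against the point null.
Equal-tail intervals are used throughout.

`complexity_anova` groups per-model mean criteria into 2/3/4/5-regressor
classes and runs the same ANOVA per criterion — the comparison that asks
whether parametric complexity buys variability-capturing ability
(adjusted R^2) without moving the flexibility criteria (AIC/AICc/BIC).

## Synthetic herd

The generator emulates a small official-recording herd: first control
21.21 +/- 13.71 d after kidding (floored at 5), 4.80 +/- 2.86 controls
per lactation (floored at 2), ~30 d spacing with +/-4 d jitter,
3.91 +/- 2.01 lactations per goat, lactation end uniform on 210-240 d.
Component values are a catalogue curve (per-goat parameters drawn around
the model's typical vector, default diagonal 5% spread; 10% on the SCC
level, where herd infection status dominates dispersion) times
multiplicative noise: Gaussian factors for percentages, lognormal for
SCC, with CVs 14.1 / 21.7 / 10.0 / 6.6 / 148.7 % for protein / fat / dry
matter / lactose / SCC.  Multiplicative noise keeps the CV constant along
the lactation, matching the single per-component CV that recording
schemes report.  Component levels center at 4, 5, 14, 5 (%) and 8e5
cells/mL.  Ground-truth per-goat parameters go to a sidecar for recovery
tests, and `mastitis_spike` scales SCC over a window to emulate clinical
events.

The default Ali-Schaeffer preset is deliberately a full five-parameter
shape: high transition-milk values in the first days, dilution to a nadir
near peak yield, recovery and a late plateau, with curvature in both the
polynomial and logarithmic regressors.  Smooth J-shaped presets are
almost perfectly absorbed by three-parameter multiplicative curves (a
Wood curve with negative power and rate is itself J-shaped), which would
make the generating model unidentifiable by adjusted R^2 — contrary to
what individual-curve field data show.  With this preset, three- and
four-parameter competitors leave about 11% of curve variance unexplained.

**What the synthetic tests do not show.**  Generated herds have no
seasonal, parity, farm or pedigree structure, no missing-at-random
pattern beyond sparse SCC sampling, Gaussian/lognormal noise only, and a
single generating family per run.  Passing identification and recovery
tests therefore demonstrates the machinery is correct and calibrated, not
that any particular model is best for a real herd.

## Problem sizes and numerics

Test and acceptance runs use herds of 8-60 goats (up to 500 for
distributional checks), series of 8-32 controls, 50-replicate
identification experiments, 200-1000-replicate calibration loops, and
the full 49-model catalogue in the end-to-end run — sizes chosen so each
property is measured with comfortable Monte-Carlo margin.  Quadratures:
adaptive for BF10 (cross-checked against a 4001-point dense-matrix
Simpson oracle at 1e-4 relative), 2001-point rho grids for the
correlation posterior.  Gradients are validated against
sensitivity-scaled Richardson-extrapolated central differences at 1e-6.
Degenerate inputs (constant series, all-zero residuals, single-sign runs,
groups of one) return missing values or typed errors rather than NaNs
propagating silently.

## Known limitations

* RP/NP carry the 30-day monthly-control assumption; with very uneven
  recording the trapezoidal MP210 is the defensible summary (the package
  warns rather than reweighting).
* Appendix-only model names were mapped to canonical literature forms;
  if the original source used a different parameterization of the same
  name, per-model fitted criteria are unaffected in kind but not
  comparable coefficient-by-coefficient.
* The JZS posterior sampler is exact only conditional on the gridded g
  marginal (401 log-spaced nodes); Bayes factors themselves use adaptive
  quadrature and are grid-free.
* No mixed/random-regression machinery, heteroscedastic weighting, or
  multiphasic fitting; these are different tools.
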