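"""Model-selection criteria and per-model ranking.

For each converged fit the module computes the explicative and predictive
criteria used to compare lactation-curve models:

* adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1), with k the number of
  curve parameters; reported as-is (may be negative for poor fits);
* the overfit ratio adj R^2 / R^2 (flagged when in [0, 0.4]);
* Gaussian least-squares information criteria
  AIC = n ln(RSS/n) + 2k, AICc = AIC + 2k(k+1)/(n-k-1),
  BIC = n ln(RSS/n) + k ln n (the residual-variance +1 is omitted
  consistently, so model comparisons are unaffected);
* MSPE = RSS/n (in-sample) and the leave-one-out cross-validated MMSE
  (explicit n-fold refit, each fold warm-started from the full-data
  solution).

``rank_models`` aggregates a sweep into a per-model table (means/SDs over
converged individuals only) ranked primarily by mean adjusted R^2, ties
broken by fewer parameters then lower BIC.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .catalogue import get_model
from .fitting import FitResult, SweepResult, fit_series
from .io import ComponentSeries

__all__ = [
    "adjusted_r2", "overfit_ratio", "information_criteria", "mspe",
    "loocv_mmse", "rank_models",
]

EXACT_FIT = -math.inf  # sentinel for rss == 0 in information criteria

# LOOCV is a pure function of (series, model, settings); memoized like fits
_LOOCV_CACHE: dict = {}


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination; NaN when n <= k + 1."""
    if n <= k + 1:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def overfit_ratio(adj_r2: float, r2: float) -> tuple[float, bool]:
    """adj R^2 / R^2 and an overfit flag (ratio in [0, 0.4])."""
    if not np.isfinite(r2) or r2 <= 0:
        return np.nan, False
    ratio = adj_r2 / r2
    return ratio, bool(0.0 <= ratio <= 0.4)


def information_criteria(rss: float, n: int, k: int
                         ) -> tuple[float, float, float]:
    """(AIC, AICc, BIC) under the Gaussian least-squares likelihood."""
    if n <= k + 1:
        return np.nan, np.nan, np.nan
    if rss <= 0:
        return EXACT_FIT, EXACT_FIT, EXACT_FIT
    aic = n * math.log(rss / n) + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    bic = n * math.log(rss / n) + k * math.log(n)
    return aic, aicc, bic


def mspe(fit: FitResult) -> float:
    """In-sample mean squared prediction error, RSS/n."""
    if not fit.converged:
        return np.nan
    return fit.rss / fit.n


def loocv_mmse(series: ComponentSeries | tuple, model, *, tol: float = 1e-8,
               max_iter: int = 200) -> tuple[float, int]:
    """Leave-one-out cross-validated mean squared prediction error.

    Each fold refits on the remaining n-1 points warm-started from the
    full-data solution (deterministic); folds that fail to converge are
    dropped and counted.  Returns (MMSE, n_dropped); MMSE is NaN when every
    fold fails.
    """
    if isinstance(series, ComponentSeries):
        t, y = series.t, series.y
    else:
        t, y = np.asarray(series[0], float), np.asarray(series[1], float)
    spec = get_model(model) if isinstance(model, str) else model
    n, k = len(t), spec.n_params
    if n <= k + 2:
        return np.nan, 0
    key = (spec.code, t.tobytes(), y.tobytes(), tol, max_iter)
    if key in _LOOCV_CACHE:
        return _LOOCV_CACHE[key]
    full = fit_series((t, y), spec, tol=tol, max_iter=max_iter)
    errors, dropped = [], 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = _warm_fit(spec, t[mask], y[mask],
                         full.b if full.converged else None,
                         tol=tol, max_iter=max_iter)
        if fold is None:
            dropped += 1
            continue
        pred = float(spec(fold, np.array([t[i]]))[0])
        errors.append((y[i] - pred) ** 2)
    if not errors:
        out = (np.nan, dropped)
    else:
        out = (float(np.mean(errors)), dropped)
    if len(_LOOCV_CACHE) < 100_000:
        _LOOCV_CACHE[key] = out
    return out


def _warm_fit(spec, t, y, b_start, *, tol, max_iter) -> Optional[np.ndarray]:
    if b_start is not None:
        return _polish(spec, t, y, b_start, tol, max_iter)
    from .fitting import CurveRegressor

    est = CurveRegressor(model=spec, tol=tol, max_iter=max_iter)
    est.fit(t, y)
    return est.coef_ if est.converged_ else None


def _polish(spec, t, y, b_start, tol, max_iter) -> Optional[np.ndarray]:
    from scipy.optimize import least_squares

    def fun(b):
        with np.errstate(all="ignore"):
            pred = spec(b, t)
        return y - np.where(np.isfinite(pred), pred, 1e10)

    def jac(b):
        with np.errstate(all="ignore"):
            J = spec.jacobian(b, t)
        return np.where(np.isfinite(J), -J, 0.0)

    try:
        res = least_squares(fun, np.asarray(b_start, float), jac=jac,
                            method="lm", ftol=tol, xtol=1e-12, gtol=1e-12,
                            max_nfev=max_iter * max(3, spec.n_params))
    except Exception:
        return None
    return res.x if np.all(np.isfinite(res.x)) else None


def _per_fit_criteria(fit: FitResult) -> dict:
    r2 = fit.r2
    adj = adjusted_r2(r2, fit.n, fit.k) if np.isfinite(r2) else np.nan
    aic, aicc, bic = (information_criteria(fit.rss, fit.n, fit.k)
                      if fit.converged else (np.nan,) * 3)
    ratio, flag = overfit_ratio(adj, r2)
    return {"model": fit.model, "component": fit.component,
            "goat_id": fit.goat_id, "converged": fit.converged,
            "n": fit.n, "k": fit.k, "rss": fit.rss if fit.converged else np.nan,
            "r2": r2, "adj_r2": adj, "aic": aic, "aicc": aicc, "bic": bic,
            "mspe": mspe(fit), "overfit_ratio": ratio, "overfit_flag": flag}


def rank_models(sweep_result: SweepResult, *,
                mmse: Optional[pd.Series] = None) -> pd.DataFrame:
    """Aggregate a sweep into a ranked per-model selection report.

    Means/SDs are taken over converged individuals only; the primary ranking
    key is mean adjusted R^2 (descending), ties broken by fewer parameters,
    then lower mean BIC.  Models with no converged fit rank last with
    missing criteria.  ``mmse`` (indexed by model code) is merged when given.
    """
    per_fit = pd.DataFrame([_per_fit_criteria(f) for f in sweep_result.fits])
    conv = per_fit[per_fit["converged"]]
    agg = conv.groupby("model").agg(
        mean_adj_r2=("adj_r2", "mean"), sd_adj_r2=("adj_r2", "std"),
        mean_rss=("rss", "mean"), mean_mspe=("mspe", "mean"),
        mean_aic=("aic", "mean"), mean_aicc=("aicc", "mean"),
        mean_bic=("bic", "mean"),
        overfit_flag=("overfit_flag", "any"),
    )
    report = pd.DataFrame(index=pd.Index(sorted(per_fit["model"].unique()),
                                         name="model"))
    report = report.join(agg).join(sweep_result.percent_fitted)
    report["percent_fitted"] = report["percent_fitted"].fillna(0.0)
    report["k"] = [get_model(m).n_params for m in report.index]
    report["regressor_count"] = [get_model(m).regressor_count
                                 for m in report.index]
    if mmse is not None:
        report = report.join(mmse.rename("mean_mmse"))
    sort_key = report.assign(
        _adj=report["mean_adj_r2"].fillna(-np.inf),
        _bic=report["mean_bic"].fillna(np.inf),
    ).sort_values(["_adj", "k", "_bic"], ascending=[False, True, True])
    report = report.loc[sort_key.index]
    report["rank"] = np.arange(1, len(report) + 1)
    return report
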