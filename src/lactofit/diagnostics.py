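"""Residual assumption tests: normality, homoscedasticity, independence.

The battery mirrors what is routinely run on lactation-curve residuals:

* Shapiro-Francia W' for normality (squared correlation between order
  statistics and Blom expected normal scores, Royston's log-normal
  p-value approximation for 5 <= n <= 5000);
* Levene's test for homoscedasticity (mean-centered by default, matching
  the common statistical-package default; median-centering available);
* Durbin-Watson for first-order autocorrelation, applied to the day-mean
  residual series across goats (residuals averaged per day in milk, so the
  sequence is an ordered series) or to a single ordered series;
* a sign runs test (normal approximation) for independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

__all__ = [
    "ResidualTestReport", "durbin_watson", "runs_test", "shapiro_francia",
    "levene", "day_mean_residuals", "residual_report",
]


@dataclass(frozen=True)
class ResidualTestReport:
    test: str
    statistic: float
    p_value: Optional[float]
    n: int
    decision: str = ""


def durbin_watson(residuals: Sequence[float]) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]; < 2 means positive
    first-order autocorrelation.  Residuals must be ordered (by DIM)."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("Durbin-Watson needs at least 2 ordered residuals")
    if np.allclose(e, 0):
        return np.nan
    return float(_sm_dw(e))


def runs_test(residuals: Sequence[float]) -> ResidualTestReport:
    """Sign runs test (normal approximation), two-sided at 0.05.

    Zeros are dropped.  z = (R - mu_R)/sigma_R with
    mu_R = 2 n1 n2/(n1+n2) + 1 and the standard variance.
    """
    e = np.asarray(residuals, dtype=float)
    signs = np.sign(e[e != 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return ResidualTestReport("runs", np.nan, None, n,
                                  decision="not applicable (one sign only)")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1))
    z = (runs - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    decision = "dependent" if p < 0.05 else "independent"
    return ResidualTestReport("runs", float(z), float(p), n, decision)


def _blom_scores(n: int) -> np.ndarray:
    i = np.arange(1, n + 1)
    return stats.norm.ppf((i - 3.0 / 8.0) / (n + 1.0 / 4.0))


def shapiro_francia(x: Sequence[float]) -> ResidualTestReport:
    """Shapiro-Francia W' with Royston's (1993) p-value approximation.

    W' is the squared Pearson correlation between the order statistics of x
    and the expected standard-normal scores at Blom plotting positions;
    location/scale invariant by construction.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 5:
        raise ValueError("Shapiro-Francia needs n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Francia undefined for constant input")
    m = _blom_scores(n)
    w = float(np.corrcoef(x, m)[0, 1] ** 2)
    # Royston 1993 normalization of ln(1 - W')
    u = math.log(n)
    v = math.log(u)
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    if w >= 1.0:
        return ResidualTestReport("shapiro_francia", 1.0, 1.0, n, "normal")
    z = (math.log(1.0 - w) - mu) / sigma
    p = float(stats.norm.sf(z))
    return ResidualTestReport("shapiro_francia", w, p, n,
                              "non-normal" if p < 0.05 else "normal")


def levene(groups: Iterable[Sequence[float]], *, center: str = "mean"
           ) -> ResidualTestReport:
    """Levene W on absolute deviations from group centers.

    ``center`` is "mean" (classical Levene, the default) or "median"
    (Brown-Forsythe).  Groups with fewer than 2 points are dropped with a
    warning.
    """
    import warnings

    kept = [np.asarray(g, dtype=float) for g in groups]
    good = [g for g in kept if len(g) >= 2]
    if len(good) < len(kept):
        warnings.warn("levene: dropped degenerate group(s) with n < 2",
                      stacklevel=2)
    if len(good) < 2:
        raise ValueError("Levene needs at least 2 non-degenerate groups")
    w, p = stats.levene(*good, center=center)
    n = int(sum(len(g) for g in good))
    return ResidualTestReport("levene", float(w), float(p), n,
                              "heteroscedastic" if p < 0.05 else
                              "homoscedastic")


def day_mean_residuals(fits: Iterable, model: Optional[str] = None,
                       component: Optional[str] = None) -> pd.Series:
    """Average residual per day in milk across goats, ordered by DIM.

    Builds the ordered series on which the Durbin-Watson statistic is
    meaningful when residuals come from many short individual series.
    ``fits`` is an iterable of FitResult carrying residuals; the original
    DIM vector must be attached as ``fit.dims`` by the caller, or pass
    (dims, residuals) pairs directly.
    """
    buckets: dict[float, list[float]] = {}
    for item in fits:
        if hasattr(item, "residuals"):
            if model is not None and item.model != model:
                continue
            if component is not None and item.component != component:
                continue
            dims = getattr(item, "dims", None)
            resid = item.residuals
        else:
            dims, resid = item
        if resid is None or dims is None:
            continue
        for d, r in zip(dims, resid):
            buckets.setdefault(float(d), []).append(float(r))
    days = sorted(buckets)
    return pd.Series([float(np.mean(buckets[d])) for d in days],
                     index=pd.Index(days, name="dim"), name="mean_residual")


def residual_report(dims_resid_pairs: Iterable[tuple], *,
                    groups: Optional[list] = None) -> pd.DataFrame:
    """Run the full battery on pooled residuals of one model x component."""
    pooled, day_series = [], day_mean_residuals(dims_resid_pairs := list(
        dims_resid_pairs))
    for _, r in dims_resid_pairs:
        pooled.extend(np.asarray(r, float))
    pooled = np.asarray(pooled)
    rows = []
    sf = shapiro_francia(pooled)
    rows.append(("shapiro_francia", sf.statistic, sf.p_value, sf.n, sf.decision))
    dw = durbin_watson(day_series.to_numpy())
    rows.append(("durbin_watson", dw, None, len(day_series),
                 "positive autocorrelation" if dw < 2 else
                 "negative autocorrelation" if dw > 2 else "none"))
    rt = runs_test(day_series.to_numpy())
    rows.append(("runs", rt.statistic, rt.p_value, rt.n, rt.decision))
    if groups is not None:
        lv = levene(groups)
        rows.append(("levene", lv.statistic, lv.p_value, lv.n, lv.decision))
    return pd.DataFrame(rows, columns=["test", "statistic", "p_value", "n",
                                       "decision"])
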