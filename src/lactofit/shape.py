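"""Curve shape parameters: peak and persistency.

The peak is the interior maximum of a fitted curve on the lactation window
(default [1, 210] days); models with a registered closed form (e.g. Wood
t* = b1/b2, parabolic yield-density t* = -b1/(2 b2)) use it, the rest are
maximized numerically (coarse grid bracket + bounded scalar refinement).
Monotone curves have no peak; for those the net fitted change per control
event is reported instead.

Persistency — how slowly the curve declines after the peak — has three
operational definitions, selected per call:

* ``post_peak_rate``: average decline (y(t_end) - y_peak)/(t_end - t_peak);
* ``halfway_relative_rate``: relative rate y'(t_h)/y(t_h) at the point
  halfway between peak and end of lactation (invariant to rescaling y);
* ``instantaneous_rate``: y'(t) at a caller-supplied day.

Derivatives are analytic (symbolic, from the catalogue) with a central
finite-difference fallback (h = 1e-4 day) for curves supplied as bare
callables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .catalogue import ModelSpec, get_model

__all__ = ["ShapeReport", "find_peak", "persistency", "change_per_event",
           "shape_report"]

PERSISTENCY_METHODS = ("post_peak_rate", "halfway_relative_rate",
                       "instantaneous_rate")


@dataclass(frozen=True)
class ShapeReport:
    model: str
    t_peak: Optional[float]
    y_peak: Optional[float]
    persistency: Optional[float]
    persistency_method: str
    change_per_event: Optional[float]
    method: str  # analytic | numeric


def _numeric_peak(spec, b, window) -> Optional[tuple[float, float]]:
    lo, hi = window
    grid = np.linspace(lo, hi, 2049)
    with np.errstate(all="ignore"):
        vals = spec(b, grid)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{spec.code}: curve non-finite on window {window}")
    i = int(np.argmax(vals))
    if i == 0 or i == len(grid) - 1:
        return None  # boundary maximum: monotone on the window
    a, c = grid[i - 1], grid[i + 1]
    # refine on the derivative where available: value-based search cannot
    # localize flat maxima below the FP noise floor
    if hasattr(spec, "dydt"):
        da = float(spec.dydt(b, np.array([a]))[0])
        dc = float(spec.dydt(b, np.array([c]))[0])
        if da > 0 > dc:
            t_star = float(brentq(
                lambda x: float(spec.dydt(b, np.array([x]))[0]), a, c,
                xtol=1e-10))
            return t_star, float(spec(b, np.array([t_star]))[0])
    res = minimize_scalar(lambda x: -float(spec(b, np.array([x]))[0]),
                          bounds=(a, c), method="bounded",
                          options={"xatol": 1e-9})
    t_star = float(res.x)
    return t_star, float(spec(b, np.array([t_star]))[0])


def find_peak(model: ModelSpec | str, b, window=(1.0, 210.0)
              ) -> Optional[tuple[float, float]]:
    """(t_peak, y_peak) of the fitted curve, or None for monotone curves.

    Uses the registered closed form when available and inside the window,
    falling back to numeric maximization otherwise.
    """
    spec = get_model(model) if isinstance(model, str) else model
    b = np.asarray(b, dtype=float)
    if spec.analytic_peak is not None:
        t_star = spec.analytic_peak(b)
        if t_star is not None and window[0] < t_star < window[1]:
            return float(t_star), float(spec(b, np.array([t_star]))[0])
        if t_star is not None:
            return None  # stationary point exists but outside the window
    return _numeric_peak(spec, b, window)


def _dydt(spec, b, t: float) -> float:
    if hasattr(spec, "dydt"):
        return float(spec.dydt(b, np.array([t]))[0])
    h = 1e-4
    f = lambda x: float(spec(b, np.array([x]))[0])
    return (f(t + h) - f(t - h)) / (2 * h)


def persistency(model: ModelSpec | str, b, t_peak: Optional[float],
                t_end: float = 210.0, method: str = "halfway_relative_rate",
                at: Optional[float] = None) -> float:
    """Post-peak decline rate under one of the three definitions.

    ``at`` supplies the evaluation day for ``instantaneous_rate``.
    """
    if method not in PERSISTENCY_METHODS:
        raise ValueError(f"method must be one of {PERSISTENCY_METHODS}")
    spec = get_model(model) if isinstance(model, str) else model
    b = np.asarray(b, dtype=float)
    if method == "instantaneous_rate":
        if at is None:
            raise ValueError("instantaneous_rate requires `at=`")
        return _dydt(spec, b, float(at))
    if t_peak is None:
        raise ValueError(f"{method} requires a peak")
    if method == "post_peak_rate":
        if t_peak >= t_end:
            raise ValueError("post_peak_rate undefined when t_peak >= t_end")
        y_peak = float(spec(b, np.array([t_peak]))[0])
        y_end = float(spec(b, np.array([t_end]))[0])
        return (y_end - y_peak) / (t_end - t_peak)
    t_h = (t_peak + t_end) / 2.0
    y_h = float(spec(b, np.array([t_h]))[0])
    if y_h == 0:
        raise ValueError("halfway_relative_rate undefined: y(t_h) = 0")
    return _dydt(spec, b, t_h) / y_h


def change_per_event(series_t, fit_b, model: ModelSpec | str) -> float:
    """Net fitted change per control event, for peakless (monotone) curves.

    (fitted value at last observed DIM - fitted value at first observed DIM)
    divided by (number of controls - 1); units of the component per control.
    This is a reporting convention, flagged as such in pipeline output.
    """
    t = np.asarray(series_t, dtype=float)
    if len(t) < 2:
        return np.nan
    spec = get_model(model) if isinstance(model, str) else model
    b = np.asarray(fit_b, dtype=float)
    y0 = float(spec(b, np.array([t[0]]))[0])
    y1 = float(spec(b, np.array([t[-1]]))[0])
    return (y1 - y0) / (len(t) - 1)


def shape_report(model: ModelSpec | str, b, series_t=None, *,
                 window=(1.0, 210.0), t_end: float = 210.0,
                 method: str = "halfway_relative_rate") -> ShapeReport:
    """Peak + persistency for one fitted curve; change-per-event fallback."""
    spec = get_model(model) if isinstance(model, str) else model
    b = np.asarray(b, dtype=float)
    if series_t is not None:
        lo = max(window[0], float(np.min(series_t)))
        hi = min(window[1], float(np.max(series_t)))
        if hi > lo:
            window = (lo, hi)
    peak = find_peak(spec, b, window)
    how = "analytic" if spec.analytic_peak is not None else "numeric"
    if peak is None:
        cpe = (change_per_event(series_t, b, spec)
               if series_t is not None else None)
        pers = (persistency(spec, b, None, t_end, "instantaneous_rate",
                            at=(window[0] + window[1]) / 2)
                if method == "instantaneous_rate" else None)
        return ShapeReport(spec.code, None, None, pers, method, cpe, how)
    t_pk, y_pk = peak
    at = (t_pk + t_end) / 2 if method == "instantaneous_rate" else None
    pers = persistency(spec, b, t_pk, t_end, method, at=at)
    return ShapeReport(spec.code, t_pk, y_pk, pers, method, None, how)
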