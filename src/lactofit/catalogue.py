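"""Registry of lactation-curve models for milk-component series.

Each entry couples a symbolic equation ``y = f(t; b0..b4)`` (``t`` = days in
milk) with the metadata needed to fit and interrogate it: parameter count,
admissible bounds, a deterministic data-driven initializer, a typical
parameter vector at a given component level (used by the synthetic-herd
generator), and, where a closed form exists, the peak location.

Equations are stored as :mod:`sympy` expressions so that exact gradients
(with respect to the parameters, for Levenberg-Marquardt) and time
derivatives (for persistency) are generated symbolically and lambdified to
fast numpy callables once per model.

The registry is data-driven: adding a model is a single ``_register`` call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "ModelSpec",
    "REGISTRY",
    "get_model",
    "list_models",
    "evaluate",
    "gradient",
    "default_init",
]

# Symbols shared by every equation.  DIM is the standardized lactation length
# entering the Ali-Schaeffer regressors; K is the spline knot.
_t = sp.Symbol("t", positive=True)
_b = sp.symbols("b0 b1 b2 b3 b4")
_DIM = sp.Symbol("DIM", positive=True)
_K = sp.Symbol("K", positive=True)

DEFAULT_DIM = 210.0
DEFAULT_KNOT = 105.0


class UnknownModelError(KeyError):
    """Raised when a model code is not in the registry."""


class DomainError(ValueError):
    """Raised when t or b violates a model's domain."""


@dataclass
class ModelSpec:
    """One lactation-curve model: equation plus fitting metadata."""

    code: str
    expr: sp.Expr
    n_params: int
    regressor_count: int
    bounds: tuple  # ((lo, hi), ...) per parameter, used for validation/draws
    reference: str
    t_positive: bool = True
    initializer: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    typical: Optional[Callable[[float], np.ndarray]] = None
    analytic_peak: Optional[Callable[[np.ndarray], Optional[float]]] = None
    constants: dict = field(default_factory=dict)
    _f: Callable = field(default=None, repr=False)
    _jac_cols: tuple = field(default=None, repr=False)
    _dydt: Callable = field(default=None, repr=False)

    @property
    def params(self) -> tuple:
        return _b[: self.n_params]

    def __post_init__(self) -> None:
        free = {s.name for s in self.expr.free_symbols}
        used = [p for p in _b if p.name in free]
        if len(used) != self.n_params:
            raise ValueError(
                f"{self.code}: equation reads {len(used)} parameters, "
                f"n_params={self.n_params}"
            )
        expr = self.expr.subs({_DIM: self.constants.get("DIM", DEFAULT_DIM),
                               _K: self.constants.get("K", DEFAULT_KNOT)})
        args = (_t,) + self.params
        self._f = sp.lambdify(args, expr, modules="numpy")
        self._jac_cols = tuple(
            sp.lambdify(args, sp.diff(expr, p), modules="numpy") for p in self.params
        )
        self._dydt = sp.lambdify(args, sp.diff(expr, _t), modules="numpy")

    # -- numeric surface ---------------------------------------------------
    def __call__(self, b: Sequence[float], t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self._f(t, *np.asarray(b, dtype=float))
        return np.broadcast_to(np.asarray(out, dtype=float), t.shape).copy()

    def jacobian(self, b: Sequence[float], t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        b = np.asarray(b, dtype=float)
        cols = [np.broadcast_to(np.asarray(c(t, *b), dtype=float), t.shape)
                for c in self._jac_cols]
        return np.column_stack(cols)

    def dydt(self, b: Sequence[float], t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = self._dydt(t, *np.asarray(b, dtype=float))
        return np.broadcast_to(np.asarray(out, dtype=float), t.shape).copy()

    def validate(self, b: Sequence[float], t: np.ndarray) -> None:
        t = np.asarray(t, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(b) != self.n_params:
            raise DomainError(
                f"{self.code}: expected {self.n_params} parameters, got {len(b)}")
        if self.t_positive and np.any(t <= 0):
            raise DomainError(f"{self.code}: t must be > 0")
        for val, (lo, hi) in zip(b, self.bounds):
            if not (lo <= val <= hi):
                raise DomainError(
                    f"{self.code}: parameter value {val} outside bounds [{lo}, {hi}]")

    def bind(self, **constants) -> "ModelSpec":
        """Return a copy with DIM/K constants rebound (e.g. a per-series knot)."""
        merged = {**self.constants, **constants}
        return ModelSpec(
            code=self.code, expr=self.expr, n_params=self.n_params,
            regressor_count=self.regressor_count, bounds=self.bounds,
            reference=self.reference, t_positive=self.t_positive,
            initializer=self.initializer, typical=self.typical,
            analytic_peak=self.analytic_peak, constants=merged,
        )

    def equation_str(self) -> str:
        return str(self.expr)


# ---------------------------------------------------------------------------
# Initializers.  Each is deterministic and maps (t, y) -> starting vector.
# Linear-in-parameter models and models with an exact linearizing transform
# solve a least-squares problem (exact on noise-free data); the remainder use
# a coarse deterministic grid over the stiff parameter(s) followed by a
# conditional linear solve.
# ---------------------------------------------------------------------------

def _lstsq(design: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return sol


def _init_linear(cols: Callable[[np.ndarray], np.ndarray]):
    def init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _lstsq(cols(t), y)
    return init


def _init_logdesign(cols: Callable[[np.ndarray], np.ndarray],
                    back: Callable[[np.ndarray], np.ndarray]):
    """ln y regressed on a design; `back` maps the linear solution to b."""
    def init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
        yy = np.maximum(y, 1e-12)
        return back(_lstsq(cols(t), np.log(yy)))
    return init


def _init_recip(cols: Callable[[np.ndarray], np.ndarray]):
    def init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
        yy = np.where(np.abs(y) < 1e-12, 1e-12, y)
        return _lstsq(cols(t), 1.0 / yy)
    return init


def _grid_then_linear(grid_param_values: np.ndarray,
                      design_for: Callable[[np.ndarray, float], np.ndarray],
                      assemble: Callable[[np.ndarray, float], np.ndarray]):
    """Scan a 1-d grid over a stiff parameter; solve the rest linearly."""
    def init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
        best, best_rss = None, np.inf
        for gv in grid_param_values:
            X = design_for(t, gv)
            sol = _lstsq(X, y)
            rss = float(np.sum((y - X @ sol) ** 2))
            if rss < best_rss:
                best_rss, best = rss, assemble(sol, gv)
        return best
    return init


# ---------------------------------------------------------------------------
# Registry construction
# ---------------------------------------------------------------------------

REGISTRY: dict[str, ModelSpec] = {}

_FREE = (-np.inf, np.inf)
_POS = (1e-12, np.inf)


def _register(code, expr, n_params, bounds, reference, *, t_positive=True,
              initializer=None, typical=None, analytic_peak=None,
              regressor_count=None):
    spec = ModelSpec(
        code=code, expr=expr, n_params=n_params,
        regressor_count=regressor_count if regressor_count is not None else n_params,
        bounds=tuple(bounds), reference=reference, t_positive=t_positive,
        initializer=initializer, typical=typical, analytic_peak=analytic_peak,
    )
    if code in REGISTRY:
        raise ValueError(f"duplicate model code {code}")
    REGISTRY[code] = spec
    return spec


b0, b1, b2, b3, b4 = _b
t = _t
ln = sp.log
exp = sp.exp

# -- polynomial / linear-in-parameter family --------------------------------

_register(
    "SIMLIN", b0 + b1 * t, 2, [_FREE, _FREE], "simple linear regression",
    t_positive=False,
    initializer=_init_linear(lambda tt: np.column_stack([np.ones_like(tt), tt])),
    typical=lambda L: np.array([1.05 * L, -5e-4 * L]),
)

_register(
    "QUADRT", b0 + b1 * t + b2 * t**2, 3, [_FREE, _FREE, _FREE],
    "quadratic polynomial", t_positive=False,
    initializer=_init_linear(
        lambda tt: np.column_stack([np.ones_like(tt), tt, tt**2])),
    typical=lambda L: np.array([0.9 * L, 2e-3 * L, -1e-5 * L]),
    analytic_peak=lambda b: (-b[1] / (2 * b[2])) if b[2] < 0 else None,
)

_register(
    "CUBIC", b0 + b1 * t + b2 * t**2 + b3 * t**3, 4,
    [_FREE, _FREE, _FREE, _FREE], "cubic polynomial", t_positive=False,
    initializer=_init_linear(
        lambda tt: np.column_stack([np.ones_like(tt), tt, tt**2, tt**3])),
    typical=lambda L: np.array([0.9 * L, 2.5e-3 * L, -2e-5 * L, 4e-8 * L]),
)

_register(
    "QDCMLOG", b0 + b1 * t + b2 * t**2 + b3 * ln(t), 4,
    [_FREE, _FREE, _FREE, _FREE], "quadratic-cum-log",
    initializer=_init_linear(
        lambda tt: np.column_stack([np.ones_like(tt), tt, tt**2, np.log(tt)])),
    typical=lambda L: np.array([0.85 * L, 8e-4 * L, -5e-6 * L, 0.04 * L]),
)

_ALISCH_X = t / _DIM
_register(
    "ALISCH",
    b0 + b1 * _ALISCH_X + b2 * _ALISCH_X**2
    + b3 * ln(_DIM / t) + b4 * ln(_DIM / t) ** 2,
    5, [_FREE] * 5, "Ali & Schaeffer five-parameter logarithmic",
    initializer=_init_linear(lambda tt: np.column_stack([
        np.ones_like(tt), tt / DEFAULT_DIM, (tt / DEFAULT_DIM) ** 2,
        np.log(DEFAULT_DIM / tt), np.log(DEFAULT_DIM / tt) ** 2])),
    # inverted ("atypical") component shape: high transition-milk values in
    # the first days, steep dilution to a nadir near peak yield (day ~20-40),
    # recovery and a late plateau — the pattern field studies describe for
    # protein and fat percentages, with curvature in both the polynomial and
    # the logarithmic regressors
    typical=lambda L: np.array([0.8657 * L, 1.7073 * L, -1.4250 * L,
                                -0.5968 * L, 0.1947 * L]),
)

_register(
    "WOOD", b0 * t**b1 * exp(-b2 * t), 3,
    [_POS, (-5, 5), (-1, 1)], "Wood incomplete gamma",
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), np.log(tt), -tt]),
        lambda c: np.array([math.exp(c[0]), c[1], c[2]])),
    typical=lambda L: np.array([0.62 * L, 0.18, 0.0035]),
    analytic_peak=lambda b: (b[1] / b[2]) if (b[1] > 0 and b[2] > 0) else None,
)

_register(
    "DHANOA", b0 * t**(b1 * b2) * exp(-b2 * t), 3,
    [_POS, (-1000, 1000), (-1, 1)], "Dhanoa reparameterized Wood",
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), np.log(tt), -tt]),
        lambda c: np.array([math.exp(c[0]),
                            c[1] / c[2] if abs(c[2]) > 1e-12 else 0.0,
                            c[2]])),
    typical=lambda L: np.array([0.62 * L, 51.4, 0.0035]),
)

_register(
    "WILMINK", b0 + b1 * exp(-b3 * t) + b2 * t, 4,
    [_FREE, _FREE, _FREE, (1e-4, 1.0)], "Wilmink exponential + linear",
    t_positive=False,
    initializer=_grid_then_linear(
        np.geomspace(5e-3, 0.5, 25),
        lambda tt, k: np.column_stack([np.ones_like(tt), np.exp(-k * tt), tt]),
        lambda sol, k: np.array([sol[0], sol[1], sol[2], k])),
    typical=lambda L: np.array([0.95 * L, -0.28 * L, 4e-4 * L, 0.06]),
)

_register(
    "PARYLDENS", 1 / (b0 + b1 * t + b2 * t**2), 3, [_FREE, _FREE, _FREE],
    "parabolic yield-density", t_positive=False,
    initializer=_init_recip(
        lambda tt: np.column_stack([np.ones_like(tt), tt, tt**2])),
    typical=lambda L: np.array([1.5 / L, -0.01 / L, 5e-5 / L]),
    analytic_peak=lambda b: (-b[1] / (2 * b[2])) if b[2] > 0 else None,
)

_register(
    "NELDER", t / (b0 + b1 * t + b2 * t**2), 3, [_FREE, _FREE, _FREE],
    "Nelder inverse quadratic polynomial",
    initializer=_init_recip(
        lambda tt: np.column_stack([1 / tt, np.ones_like(tt), tt])),
    typical=lambda L: np.array([9.0 / L, 0.7 / L, 0.0025 / L]),
)

_register(
    "MICHMEN", b0 * t / (b1 + t), 2, [_POS, _POS], "Michaelis-Menten",
    initializer=lambda tt, yy: _mm_init(tt, yy),
    typical=lambda L: np.array([1.08 * L, 12.0]),
)


def _mm_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # Lineweaver-Burk: 1/y = 1/b0 + (b1/b0)/t, exact on clean data
    yy = np.maximum(yy, 1e-12)
    c = _lstsq(np.column_stack([np.ones_like(tt), 1 / tt]), 1 / yy)
    v = 1.0 / max(c[0], 1e-12)
    return np.array([v, max(c[1] * v, 1e-6)])


_register(
    "POWER", b0 * t**b1, 2, [_POS, (-5, 5)], "power function",
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), np.log(tt)]),
        lambda c: np.array([math.exp(c[0]), c[1]])),
    typical=lambda L: np.array([0.82 * L, 0.045]),
)

_register(
    "GMPRTZ", b0 * exp(-b1 * exp(-b2 * t)), 3, [_POS, _POS, (1e-5, 1.0)],
    "Gompertz growth", t_positive=False,
    initializer=lambda tt, yy: _gompertz_init(tt, yy),
    typical=lambda L: np.array([1.08 * L, 0.45, 0.025]),
)


def _gompertz_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    top = 1.02 * np.max(yy)
    u = np.log(top / np.maximum(yy, 1e-12))
    u = np.maximum(u, 1e-10)
    c = _lstsq(np.column_stack([np.ones_like(tt), -tt]), np.log(u))
    return np.array([top, math.exp(c[0]), max(c[1], 1e-5)])


_register(
    "RICHRDS", b0 / (1 + b1 * exp(-b2 * t)) ** (1 / b3), 4,
    [_POS, _POS, (1e-5, 1.0), (1e-3, 20)], "Richards growth",
    t_positive=False,
    typical=lambda L: np.array([1.1 * L, 1.0, 0.03, 1.0]),
)

_register(
    "METLAW", b0 - b1 * exp(-b2 * t), 3, [_FREE, _FREE, (1e-5, 1.0)],
    "Mitscherlich law of diminishing returns / asymptotic regression",
    t_positive=False,
    initializer=lambda tt, yy: _metlaw_init(tt, yy),
    typical=lambda L: np.array([1.04 * L, 0.35 * L, 0.02]),
)


def _metlaw_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    top = np.max(yy) + 0.05 * (np.ptp(yy) + 1e-9)
    u = np.maximum(top - yy, 1e-12)
    c = _lstsq(np.column_stack([np.ones_like(tt), -tt]), np.log(u))
    return np.array([top, math.exp(c[0]), max(c[1], 1e-5)])


_register(
    "MORMFLO", (b0 * b1 + b2 * t**b3) / (b1 + t**b3), 4,
    [_FREE, _POS, _FREE, (1e-3, 10)], "Morgan-Mercer-Flodin",
    typical=lambda L: np.array([0.72 * L, 60.0, 1.12 * L, 1.4]),
)

_register(
    "VBRTLNFY", b0 * (1 - b1 * exp(-b2 * t)) ** 3, 3,
    [_POS, (-10, 1.0 - 1e-9), (1e-5, 1.0)], "von Bertalanffy growth",
    t_positive=False,
    initializer=lambda tt, yy: _vbert_init(tt, yy),
    typical=lambda L: np.array([1.05 * L, 0.22, 0.03]),
)


def _vbert_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    top = 1.02 * np.max(yy)
    u = 1.0 - np.cbrt(np.maximum(yy, 1e-12) / top)
    u = np.maximum(u, 1e-10)
    c = _lstsq(np.column_stack([np.ones_like(tt), -tt]), np.log(u))
    return np.array([top, math.exp(c[0]), max(c[1], 1e-5)])


_register(
    "PEMSIK", b0 * exp(b1 * t - b2 * t**2), 3, [_POS, _FREE, _FREE],
    "parabolic exponential (Sikka)", t_positive=False,
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), tt, -tt**2]),
        lambda c: np.array([math.exp(c[0]), c[1], c[2]])),
    typical=lambda L: np.array([0.97 * L, 8e-4, 5e-6]),
    analytic_peak=lambda b: (b[1] / (2 * b[2])) if (b[1] > 0 and b[2] > 0) else None,
)

_register(
    "SIN&GOP", b0 - b1 * t + b2 * ln(t), 3, [_FREE, _FREE, _FREE],
    "Singh & Gopal",
    initializer=_init_linear(
        lambda tt: np.column_stack([np.ones_like(tt), -tt, np.log(tt)])),
    typical=lambda L: np.array([0.85 * L, 5e-4 * L, 0.05 * L]),
)

_register(
    "GAUSS", b0 * exp(-(t - b1) ** 2 / (2 * b2**2)), 3,
    [_POS, _FREE, _POS], "Gaussian bell", t_positive=False,
    initializer=lambda tt, yy: _gauss_init(tt, yy),
    typical=lambda L: np.array([1.05 * L, 90.0, 130.0]),
    analytic_peak=lambda b: float(b[1]),
)


def _gauss_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # ln y is quadratic in t; exact on clean data
    c = _lstsq(np.column_stack([np.ones_like(tt), tt, tt**2]),
               np.log(np.maximum(yy, 1e-12)))
    if c[2] >= -1e-15:
        mu = tt[int(np.argmax(yy))]
        return np.array([float(np.max(yy)), float(mu), float(np.ptp(tt) + 1.0)])
    s2 = -1.0 / (2 * c[2])
    mu = c[1] * s2
    amp = math.exp(c[0] + mu**2 / (2 * s2))
    return np.array([amp, mu, math.sqrt(s2)])


_register(
    "CAPBOR", b0 * (exp(-b1 * t) - exp(-b2 * t)), 3,
    [_POS, (-1, 1), (-1, 5)], "Cappio-Borlino biexponential",
    t_positive=False,
    initializer=lambda tt, yy: _capbor_init(tt, yy),
    typical=lambda L: np.array([1.35 * L, 0.002, 0.09]),
)


def _capbor_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    best, best_rss = None, np.inf
    for a in np.geomspace(2e-4, 0.02, 12):
        for ratio in (5.0, 10.0, 25.0, 50.0):
            c = a * ratio
            x = np.exp(-a * tt) - np.exp(-c * tt)
            denom = float(x @ x)
            if denom < 1e-12:
                continue
            amp = float(x @ yy) / denom
            rss = float(np.sum((yy - amp * x) ** 2))
            if rss < best_rss:
                best_rss, best = rss, np.array([amp, a, c])
    return best


_register(
    "MILKBOT", b0 * (1 - exp((b1 - t) / b2) / 2) * exp(-b3 * t), 4,
    [_POS, (-100, 100), (1e-2, 500), (-1, 1)], "MilkBot",
    t_positive=False,
    initializer=lambda tt, yy: _milkbot_init(tt, yy),
    typical=lambda L: np.array([1.1 * L, -5.0, 18.0, 4e-4]),
)


def _milkbot_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # decay from the latest third of the series, ramp defaults
    n = len(tt)
    tail = slice(max(0, n - max(3, n // 3)), n)
    c = _lstsq(np.column_stack([np.ones_like(tt[tail]), -tt[tail]]),
               np.log(np.maximum(yy[tail], 1e-12)))
    d = min(max(c[1], 1e-6), 0.05)
    amp = float(np.max(yy)) * math.exp(d * tt[int(np.argmax(yy))])
    return np.array([amp, 0.0, 15.0, d])


_register(
    "QUADSPL",
    b0 + b1 * t + b2 * t**2
    + b3 * sp.Piecewise((0, t < _K), ((t - _K) ** 2, True)),
    4, [_FREE] * 4, "quadratic spline, one knot", t_positive=False,
    initializer=_init_linear(lambda tt: np.column_stack([
        np.ones_like(tt), tt, tt**2,
        np.where(tt < DEFAULT_KNOT, 0.0, (tt - DEFAULT_KNOT) ** 2)])),
    typical=lambda L: np.array([0.92 * L, 1.6e-3 * L, -1.2e-5 * L, 9e-6 * L]),
)

_register(
    "CUBSPL",
    b0 + b1 * t + b2 * t**2 + b3 * t**3
    + b4 * sp.Piecewise((0, t < _K), ((t - _K) ** 3, True)),
    5, [_FREE] * 5, "cubic spline, one knot", t_positive=False,
    initializer=_init_linear(lambda tt: np.column_stack([
        np.ones_like(tt), tt, tt**2, tt**3,
        np.where(tt < DEFAULT_KNOT, 0.0, (tt - DEFAULT_KNOT) ** 3)])),
    typical=lambda L: np.array([0.92 * L, 1.8e-3 * L, -1.6e-5 * L,
                                3e-8 * L, 6e-8 * L]),
)

_LEG_X = 2 * (t - 1) / (DEFAULT_DIM - 1) - 1
_register(
    "3ORDLEG",
    sum(_b[k] * sp.legendre(k, _LEG_X) for k in range(4)),
    4, [_FREE] * 4, "third-order Legendre polynomial", t_positive=False,
    initializer=_init_linear(lambda tt: np.column_stack([
        np.polynomial.legendre.legval(2 * (tt - 1) / (DEFAULT_DIM - 1) - 1,
                                      np.eye(4)[k]) for k in range(4)])),
    typical=lambda L: np.array([1.0 * L, -0.06 * L, 0.025 * L, -0.012 * L]),
)

# -- appendix-named slots (canonical literature parameterizations) ----------

_register(
    "CEXPGR", b0 * exp(b1 * t + b2 * t**2 + b3 * t**3), 4,
    [_POS, _FREE, _FREE, _FREE], "cubic exponential growth", t_positive=False,
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), tt, tt**2, tt**3]),
        lambda c: np.array([math.exp(c[0]), c[1], c[2], c[3]])),
    typical=lambda L: np.array([0.98 * L, 1e-3, -1e-5, 2.2e-8]),
)

_register(
    "CURVES",
    b0 + b1 * t + b2 * sp.sin(sp.pi * t / _DIM) + b3 * sp.cos(sp.pi * t / _DIM),
    4, [_FREE] * 4, "trigonometric regression", t_positive=False,
    initializer=_init_linear(lambda tt: np.column_stack([
        np.ones_like(tt), tt, np.sin(np.pi * tt / DEFAULT_DIM),
        np.cos(np.pi * tt / DEFAULT_DIM)])),
    typical=lambda L: np.array([1.0 * L, -3e-4 * L, 0.07 * L, -0.04 * L]),
)

_register(
    "DENSITY", 1 / (b0 + b1 * t), 2, [_FREE, _FREE],
    "reciprocal linear yield-density (Shinozaki-Kira)", t_positive=False,
    initializer=_init_recip(lambda tt: np.column_stack([np.ones_like(tt), tt])),
    typical=lambda L: np.array([0.92 / L, 7e-4 / L]),
)

_register(
    "DJKSTR", b0 * exp(b1 * (1 - exp(-b2 * t)) / b2 - b3 * t), 4,
    [_POS, _FREE, (1e-4, 1.0), _FREE], "Dijkstra mechanistic",
    t_positive=False,
    initializer=lambda tt, yy: _djkstr_init(tt, yy),
    typical=lambda L: np.array([0.80 * L, 0.012, 0.05, 0.0012]),
)


def _djkstr_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    lny = np.log(np.maximum(yy, 1e-12))
    best, best_rss = None, np.inf
    for k in np.geomspace(5e-3, 0.5, 20):
        X = np.column_stack([np.ones_like(tt), (1 - np.exp(-k * tt)) / k, -tt])
        sol = _lstsq(X, lny)
        rss = float(np.sum((lny - X @ sol) ** 2))
        if rss < best_rss:
            best_rss = rss
            best = np.array([math.exp(sol[0]), sol[1], k, sol[2]])
    return best


_register(
    "GROSMN", b0 * (1 - sp.tanh(b1 * (t - b2)) ** 2), 3,
    [_POS, (1e-5, 1.0), _FREE], "Grossman single-phase logistic (sech^2)",
    t_positive=False,
    initializer=lambda tt, yy: np.array(
        [float(np.max(yy)), 0.004, float(tt[int(np.argmax(yy))])]),
    typical=lambda L: np.array([1.04 * L, 0.0035, 70.0]),
)

_register(
    "HAYSHI", b0 * (1 - b1 * exp(-b2 * t)) * exp(-b3 * t), 4,
    [_POS, (-10, 1.0 - 1e-9), (1e-4, 1.0), (-0.2, 0.2)],
    "saturating-rise times exponential-decline", t_positive=False,
    typical=lambda L: np.array([1.15 * L, 0.38, 0.06, 0.0008]),
)

_register(
    "INVQPOL", 1 / (b0 + b1 / t + b2 * t), 3, [_FREE, _FREE, _FREE],
    "inverse polynomial with reciprocal term",
    initializer=_init_recip(
        lambda tt: np.column_stack([np.ones_like(tt), 1 / tt, tt])),
    typical=lambda L: np.array([0.85 / L, 0.18 / L, 5e-4 / L]),
)

_register(
    "LOGLOG", b0 + b1 * ln(t) + b2 * ln(t) ** 2, 3, [_FREE] * 3,
    "quadratic in log time",
    initializer=_init_linear(lambda tt: np.column_stack(
        [np.ones_like(tt), np.log(tt), np.log(tt) ** 2])),
    typical=lambda L: np.array([0.90 * L, 0.08 * L, -0.012 * L]),
)

_register(
    "LGMWEIB", b0 - b1 * exp(-b2 * t**b3), 4,
    [_FREE, _FREE, (1e-6, 10.0), (1e-2, 5.0)], "modified Weibull growth",
    typical=lambda L: np.array([1.05 * L, 0.4 * L, 0.01, 1.2]),
)

_register(
    "PARSURW", b0 + b1 * t + b2 * sp.sqrt(t), 3, [_FREE] * 3,
    "linear plus square-root (parabolic-in-sqrt-t)", t_positive=False,
    initializer=_init_linear(lambda tt: np.column_stack(
        [np.ones_like(tt), tt, np.sqrt(tt)])),
    typical=lambda L: np.array([0.82 * L, -4e-4 * L, 0.035 * L]),
)

_register(
    "RATCUB", (b0 + b1 * t + b2 * t**2) / (1 + b3 * t**3), 4,
    [_FREE, _FREE, _FREE, _FREE], "rational, cubic denominator",
    t_positive=False,
    initializer=lambda tt, yy: _ratcub_init(tt, yy),
    typical=lambda L: np.array([0.95 * L, 1.5e-3 * L, -6e-6 * L, 6e-9]),
)


def _ratcub_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    # y (1 + b3 t^3) = b0 + b1 t + b2 t^2  -> linear in (b0, b1, b2, b3)
    X = np.column_stack([np.ones_like(tt), tt, tt**2, -yy * tt**3])
    return _lstsq(X, yy)


_register(
    "DAVE", b0 + b1 * t + b2 * t**2, 3, [_FREE] * 3,
    "Dave quadratic (buffalo lactation)", t_positive=False,
    initializer=_init_linear(
        lambda tt: np.column_stack([np.ones_like(tt), tt, tt**2])),
    typical=lambda L: np.array([0.95 * L, 1.2e-3 * L, -6e-6 * L]),
)

# -- remaining slots: standard lactation/growth forms -----------------------

_register(
    "BRODY", b0 * exp(-b1 * t), 2, [_POS, _FREE], "Brody exponential decline",
    t_positive=False,
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), -tt]),
        lambda c: np.array([math.exp(c[0]), c[1]])),
    typical=lambda L: np.array([1.09 * L, 8e-4]),
)

_register(
    "LOGISTIC", b0 / (1 + b1 * exp(-b2 * t)), 3, [_POS, _POS, (1e-5, 1.0)],
    "logistic growth", t_positive=False,
    initializer=lambda tt, yy: _logistic_init(tt, yy),
    typical=lambda L: np.array([1.07 * L, 0.7, 0.02]),
)


def _logistic_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    top = 1.02 * np.max(yy)
    u = np.maximum(top / np.maximum(yy, 1e-12) - 1.0, 1e-10)
    c = _lstsq(np.column_stack([np.ones_like(tt), -tt]), np.log(u))
    return np.array([top, math.exp(c[0]), max(c[1], 1e-5)])


_register(
    "COBBYLD", b0 * (1 - exp(-b2 * t)) - b1 * t, 3,
    [_POS, _FREE, (1e-4, 2.0)], "Cobby & Le Du", t_positive=False,
    initializer=lambda tt, yy: _cobbyld_init(tt, yy),
    typical=lambda L: np.array([1.12 * L, 3e-4 * L, 0.09]),
)


def _cobbyld_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    best, best_rss = None, np.inf
    for k in np.geomspace(0.01, 1.0, 16):
        X = np.column_stack([1 - np.exp(-k * tt), -tt])
        sol = _lstsq(X, yy)
        rss = float(np.sum((yy - X @ sol) ** 2))
        if rss < best_rss:
            best_rss, best = rss, np.array([max(sol[0], 1e-9), sol[1], k])
    return best


_register(
    "ROOK", b0 / (1 + b1 / (b2 + t)) * exp(-b3 * t), 4,
    [_POS, _FREE, _POS, (-0.2, 0.2)], "Rook mechanistic",
    t_positive=False,
    typical=lambda L: np.array([1.12 * L, 4.0, 8.0, 0.0006]),
)

_register(
    "SCHUMCHR", b0 * exp(-b1 / t), 2, [_POS, _FREE], "Schumacher",
    initializer=_init_logdesign(
        lambda tt: np.column_stack([np.ones_like(tt), -1 / tt]),
        lambda c: np.array([math.exp(c[0]), c[1]])),
    typical=lambda L: np.array([1.02 * L, 0.6]),
)

_register(
    "TEWOOD", b0 * t * exp(-b1 * t), 2, [_POS, (1e-6, 1.0)],
    "t-times-exponential (Papajcsik-Bodero)", t_positive=False,
    initializer=lambda tt, yy: _tewood_init(tt, yy),
    typical=lambda L: np.array([L / 33.5, 0.011]),
    analytic_peak=lambda b: (1.0 / b[1]) if b[1] > 0 else None,
)


def _tewood_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    c = _lstsq(np.column_stack([np.ones_like(tt), -tt]),
               np.log(np.maximum(yy, 1e-12) / tt))
    return np.array([math.exp(c[0]), max(c[1], 1e-6)])


_register(
    "LOGEXP", b0 * ln(1 + t) * exp(-b1 * t), 2, [_POS, (1e-6, 1.0)],
    "log-rise times exponential-decline (Papajcsik-Bodero)", t_positive=False,
    initializer=lambda tt, yy: _logexp_init(tt, yy),
    typical=lambda L: np.array([L / 4.1, 0.0022]),
)


def _logexp_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    c = _lstsq(np.column_stack([np.ones_like(tt), -tt]),
               np.log(np.maximum(yy, 1e-12) / np.log(1 + tt)))
    return np.array([math.exp(c[0]), max(c[1], 1e-6)])


_register(
    "SATEXP", b0 * (1 - exp(-b1 * t)) * exp(-b2 * t), 3,
    [_POS, (1e-4, 2.0), (-0.2, 0.2)],
    "saturating exponential times decline", t_positive=False,
    initializer=lambda tt, yy: _satexp_init(tt, yy),
    typical=lambda L: np.array([1.12 * L, 0.14, 0.0009]),
)


def _satexp_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    best, best_rss = None, np.inf
    for k in np.geomspace(0.01, 1.0, 16):
        for d in (1e-4, 5e-4, 1e-3, 3e-3, 0.01):
            x = (1 - np.exp(-k * tt)) * np.exp(-d * tt)
            denom = float(x @ x)
            if denom < 1e-12:
                continue
            amp = float(x @ yy) / denom
            rss = float(np.sum((yy - amp * x) ** 2))
            if rss < best_rss:
                best_rss, best = rss, np.array([max(amp, 1e-9), k, d])
    return best


_register(
    "ATANEXP", b0 * sp.atan(b1 * t) * exp(-b2 * t), 3,
    [_POS, _POS, (-0.2, 0.2)], "arctangent times exponential (Papajcsik-Bodero)",
    t_positive=False,
    typical=lambda L: np.array([0.74 * L, 0.3, 0.0009]),
)

_register(
    "MMEXP", b0 * t / (b1 + t) * exp(-b2 * t), 3,
    [_POS, _POS, (-0.2, 0.2)], "Michaelis-Menten times exponential (Rook form)",
    t_positive=False,
    initializer=lambda tt, yy: _mmexp_init(tt, yy),
    typical=lambda L: np.array([1.15 * L, 9.0, 0.0008]),
)


def _mmexp_init(tt: np.ndarray, yy: np.ndarray) -> np.ndarray:
    best, best_rss = None, np.inf
    for d in (1e-4, 3e-4, 1e-3, 3e-3, 0.01):
        b = _mm_init(tt, yy * np.exp(d * tt))
        pred = b[0] * tt / (b[1] + tt) * np.exp(-d * tt)
        rss = float(np.sum((yy - pred) ** 2))
        if rss < best_rss:
            best_rss, best = rss, np.array([b[0], b[1], d])
    return best


_register(
    "HYPERB", b0 + b1 * t + b2 / t, 3, [_FREE] * 3,
    "linear plus hyperbolic term",
    initializer=_init_linear(
        lambda tt: np.column_stack([np.ones_like(tt), tt, 1 / tt])),
    typical=lambda L: np.array([1.02 * L, -3e-4 * L, -0.12 * L]),
)

_register(
    "BRODY24", b0 * exp(-b1 * t) - b2 * exp(-b3 * t), 4,
    [_POS, (-1, 1), _FREE, (-1, 5)], "generalized biexponential",
    t_positive=False,
    typical=lambda L: np.array([1.25 * L, 0.001, 0.45 * L, 0.05]),
)


assert len(REGISTRY) == 49, f"registry holds {len(REGISTRY)} models, expected 49"


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def get_model(code: str, **constants) -> ModelSpec:
    """Look up a model by code; optional DIM/K constants rebind the equation."""
    try:
        spec = REGISTRY[code]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {code!r}; registered: {sorted(REGISTRY)}") from None
    return spec.bind(**constants) if constants else spec


def list_models() -> "pd.DataFrame":  # noqa: F821 - import deferred
    import pandas as pd

    rows = [{
        "code": s.code, "n_params": s.n_params,
        "regressor_count": s.regressor_count,
        "equation": s.equation_str(), "reference": s.reference,
        "has_initializer": s.initializer is not None,
    } for s in REGISTRY.values()]
    return pd.DataFrame(rows)


def evaluate(model: ModelSpec | str, b: Sequence[float], t) -> np.ndarray:
    """Pointwise curve values with domain and bounds validation."""
    spec = get_model(model) if isinstance(model, str) else model
    t = np.asarray(t, dtype=float)
    spec.validate(b, t)
    return spec(b, t)


def gradient(model: ModelSpec | str, b: Sequence[float], t) -> np.ndarray:
    """d y / d b as an (n, k) matrix (analytic, via symbolic differentiation)."""
    spec = get_model(model) if isinstance(model, str) else model
    t = np.asarray(t, dtype=float)
    spec.validate(b, t)
    return spec.jacobian(b, t)


def default_init(model: ModelSpec | str, t, y) -> np.ndarray:
    """Deterministic starting values for a series.

    Uses the model's registered data-driven rule when available (exact
    transforms for linearizable models, coarse grids for stiff ones) and a
    level-scaled typical vector otherwise.  Always returns a finite vector.
    """
    spec = get_model(model) if isinstance(model, str) else model
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    b = None
    if spec.initializer is not None:
        try:
            b = np.asarray(spec.initializer(t, y), dtype=float)
        except Exception:
            b = None
    if b is None or not np.all(np.isfinite(b)):
        level = float(np.mean(y)) if len(y) else 1.0
        if spec.typical is not None:
            b = np.asarray(spec.typical(max(abs(level), 1e-9)), dtype=float)
        else:
            b = np.zeros(spec.n_params)
            b[0] = level
    # clip into bounds so downstream validation passes
    lo = np.array([bd[0] for bd in spec.bounds])
    hi = np.array([bd[1] for bd in spec.bounds])
    return np.minimum(np.maximum(b, lo), hi)
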