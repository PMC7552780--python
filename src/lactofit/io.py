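"""Test-day table I/O, per-goat component series, and yield standardization.

A test-day table is a CSV with one row per official milk control:

    goat_id, lactation_no, kidding_date, control_date, milk_kg,
    protein_pct, fat_pct, dm_pct, lactose_pct, scc

Dates are ISO-8601; days in milk (DIM) is ``control_date - kidding_date`` in
whole days.  Three whole-lactation yield summaries are provided:

* ``real_production`` (RP): first-interval yield plus 30-day-weighted
  interior controls plus a residual last interval,
  ``RP = d1*P1 + 30*sum(P2..P(n-1)) + [d2 - 30(n-2)]*Pn``;
* ``normalized_production`` (NP): the same skeleton with interval means,
  ``NP = d1*P1 + 30*sum((Pi+Pi+1)/2, i=1..n-2) + [d2 - 30(n-2)]*(P(n-1)+Pn)/2``;
* ``accumulated_yield_210`` (MP210): trapezoidal integral of the piecewise
  linear interpolant of (DIM, yield) between the first control and day 210.

RP and NP assume roughly monthly controls (the 30-day weight); a warning is
emitted when spacing departs from monthly by more than 10 days, and when the
residual last-interval bracket goes negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "COMPONENT_COLUMNS",
    "TestDayRecord",
    "ComponentSeries",
    "IntervalPair",
    "read_testday_table",
    "compute_intervals",
    "real_production",
    "normalized_production",
    "accumulated_yield_210",
    "standardize_yields",
    "build_series",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("protein", "fat", "dry_matter", "lactose", "scc")
COMPONENT_COLUMNS = {
    "protein": "protein_pct",
    "fat": "fat_pct",
    "dry_matter": "dm_pct",
    "lactose": "lactose_pct",
    "scc": "scc",
}
MANDATORY = ("goat_id", "lactation_no", "kidding_date", "control_date")


class InputFormatError(ValueError):
    """File cannot be parsed as a test-day table."""


class ValidationError(ValueError):
    """Parsed rows violate a test-day invariant."""


class InsufficientDataError(ValueError):
    """Operation requires more controls than the lactation holds."""


@dataclass(frozen=True)
class TestDayRecord:
    """One control event for one goat."""

    goat_id: str
    lactation_no: int
    kidding_date: pd.Timestamp
    control_date: pd.Timestamp
    dim: int
    milk_kg: float
    protein_pct: float
    fat_pct: float
    dm_pct: float
    lactose_pct: float
    scc: Optional[float] = None


@dataclass(frozen=True)
class ComponentSeries:
    """The fitting unit: ordered (DIM, value) pairs for one goat x component."""

    goat_id: str
    component: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(t) != len(y):
            raise ValidationError("t and y lengths differ")
        if len(t) and t[0] < 1:
            raise ValidationError("series must start at DIM >= 1")
        if np.any(np.diff(t) < 0):
            raise ValidationError("series DIM must be non-decreasing")
        if np.any(~np.isfinite(y)):
            raise ValidationError("series contains missing values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class IntervalPair:
    """d1 = kidding -> first control; d2 = penultimate -> last control (days)."""

    d1: int
    d2: int


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_testday_table(path, dialect: Optional[dict] = None) -> pd.DataFrame:
    """Read and validate a test-day CSV.

    Returns a DataFrame sorted by (goat_id, lactation_no, dim) with a ``dim``
    column added.  Rows missing a mandatory field are dropped (counted in the
    log); duplicate (goat, lactation, control_date) rows and negative DIM are
    validation errors.
    """
    try:
        df = pd.read_csv(path, **(dialect or {}))
    except Exception as exc:  # pragma: no cover - passthrough message
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in MANDATORY if c not in df.columns]
    if missing_cols:
        raise InputFormatError(f"missing mandatory columns: {missing_cols}")
    for col in ("kidding_date", "control_date"):
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except Exception as exc:
            raise InputFormatError(f"unparseable dates in {col}: {exc}") from exc

    n0 = len(df)
    df = df.dropna(subset=list(MANDATORY))
    if len(df) < n0:
        logger.info("dropped %d rows with missing mandatory fields", n0 - len(df))

    dup = df.duplicated(subset=["goat_id", "lactation_no", "control_date"])
    if dup.any():
        row = df.index[dup][0]
        raise ValidationError(
            f"duplicate (goat, lactation, control_date) at row {row}")

    df = df.copy()
    df["dim"] = (df["control_date"] - df["kidding_date"]).dt.days
    if (df["dim"] < 0).any():
        row = df.index[df["dim"] < 0][0]
        raise ValidationError(f"control before kidding at row {row}")
    for comp, col in COMPONENT_COLUMNS.items():
        if col in df.columns:
            bad = df[col].dropna() < 0
            if bad.any():
                raise ValidationError(f"negative values in {col}")
            if col != "scc" and (df[col].dropna() > 100).any():
                raise ValidationError(f"{col} outside [0, 100]")
    return df.sort_values(["goat_id", "lactation_no", "dim"],
                          kind="mergesort").reset_index(drop=True)


def to_records(df: pd.DataFrame) -> list[TestDayRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(TestDayRecord(
            goat_id=str(row.goat_id), lactation_no=int(row.lactation_no),
            kidding_date=row.kidding_date, control_date=row.control_date,
            dim=int(row.dim), milk_kg=float(row.milk_kg),
            protein_pct=float(row.protein_pct), fat_pct=float(row.fat_pct),
            dm_pct=float(row.dm_pct), lactose_pct=float(row.lactose_pct),
            scc=None if pd.isna(getattr(row, "scc", np.nan)) else float(row.scc),
        ))
    return out


# ---------------------------------------------------------------------------
# Standardizations (operate on one lactation, ordered by DIM)
# ---------------------------------------------------------------------------

def _dims_yields(dims, yields=None):
    if yields is None and hasattr(dims, "columns"):  # DataFrame of one lactation
        frame = dims.sort_values("dim")
        dims, yields = frame["dim"].to_numpy(), frame["milk_kg"].to_numpy()
    d = np.asarray(dims, dtype=float)
    p = np.asarray(yields, dtype=float)
    if np.any(np.diff(d) <= 0):
        raise ValidationError("control DIMs must be strictly increasing")
    return d, p


def compute_intervals(dims, yields=None) -> IntervalPair:
    """d1 = DIM of first control; d2 = DIM(last) - DIM(penultimate)."""
    if yields is None and hasattr(dims, "columns"):
        d, _ = _dims_yields(dims)
    else:
        d = np.asarray(dims, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValidationError("control DIMs must be strictly increasing")
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 controls")
    return IntervalPair(d1=int(d[0]), d2=int(d[-1] - d[-2]))


def _check_monthly(d: np.ndarray, label: str) -> None:
    gaps = np.diff(d)
    if len(gaps) and np.any(np.abs(gaps - 30) > 10):
        warnings.warn(
            f"{label}: control spacing departs from monthly by > 10 days; "
            "the 30-day interior weight may misrepresent the lactation",
            stacklevel=3)


def real_production(dims, yields=None) -> float:
    """RP = d1*P1 + 30*sum(interior P) + [d2 - 30(n-2)]*Pn."""
    d, p = _dims_yields(dims, yields)
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 controls")
    iv = compute_intervals(d, p)
    n = len(d)
    _check_monthly(d, "real_production")
    bracket = iv.d2 - 30.0 * (n - 2)
    if bracket < 0:
        warnings.warn("real_production: residual last-interval weight is "
                      "negative (d2 < 30(n-2)); value not clamped",
                      stacklevel=2)
    return float(iv.d1 * p[0] + 30.0 * np.sum(p[1:-1]) + bracket * p[-1])


def normalized_production(dims, yields=None) -> float:
    """NP = d1*P1 + 30*sum of interval means + residual-interval mean term."""
    d, p = _dims_yields(dims, yields)
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 controls")
    iv = compute_intervals(d, p)
    n = len(d)
    _check_monthly(d, "normalized_production")
    mids = (p[:-1] + p[1:]) / 2.0
    a = 30.0 * np.sum(mids[:-1])  # i = 1 .. n-2
    bracket = iv.d2 - 30.0 * (n - 2)
    if bracket < 0:
        warnings.warn("normalized_production: residual last-interval weight "
                      "is negative (d2 < 30(n-2)); value not clamped",
                      stacklevel=2)
    b = bracket * (p[-2] + p[-1]) / 2.0
    return float(iv.d1 * p[0] + a + b)


def accumulated_yield_210(dims, yields=None, *, truncate_at: float | None = 210.0
                          ) -> float:
    """Trapezoidal 210-day accumulated yield.

    Integrates the piecewise-linear interpolant of (DIM, yield) over
    consecutive controls; with ``truncate_at`` set (default day 210) the last
    partial interval is clipped by linear interpolation.  Pass
    ``truncate_at=None`` to integrate over the full observed range.
    """
    d, p = _dims_yields(dims, yields)
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 controls")
    if truncate_at is not None and d[-1] > truncate_at:
        if d[0] >= truncate_at:
            return 0.0
        y_cut = float(np.interp(truncate_at, d, p))
        keep = d < truncate_at
        d = np.append(d[keep], truncate_at)
        p = np.append(p[keep], y_cut)
    return float(np.trapezoid(p, d))


def standardize_yields(df: pd.DataFrame) -> pd.DataFrame:
    """Per (goat, lactation): append rp, np, mp210 columns (NaN if < 2 controls)."""
    rows = []
    for (goat, lact), g in df.groupby(["goat_id", "lactation_no"], sort=True):
        g = g.sort_values("dim")
        d, p = g["dim"].to_numpy(float), g["milk_kg"].to_numpy(float)
        if len(d) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rp = real_production(d, p)
                np_ = normalized_production(d, p)
                mp = accumulated_yield_210(d, p)
        else:
            rp = np_ = mp = np.nan
        rows.append({"goat_id": goat, "lactation_no": lact,
                     "rp": rp, "np": np_, "mp210": mp})
    return df.merge(pd.DataFrame(rows), on=["goat_id", "lactation_no"],
                    how="left")


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------

def build_series(df: pd.DataFrame, component: str, *,
                 per_lactation: bool = False) -> list[ComponentSeries]:
    """Build per-goat (default) or per-lactation component series.

    Pooling lactations stacks all of a goat's controls on the DIM axis
    (sorted, ties kept); rows with a missing value for the component are
    dropped per series, so e.g. sparse SCC sampling does not shrink the
    percentage series.
    """
    if component not in COMPONENT_COLUMNS:
        raise ValueError(f"unknown component {component!r}; "
                         f"choose from {COMPONENTS}")
    col = COMPONENT_COLUMNS[component]
    keys = ["goat_id", "lactation_no"] if per_lactation else ["goat_id"]
    out = []
    for key, g in df.groupby(keys, sort=True):
        g = g.dropna(subset=[col]).sort_values("dim", kind="mergesort")
        g = g[g["dim"] >= 1]  # day of kidding excluded; log models need t >= 1
        if g.empty:
            continue
        goat = key[0] if isinstance(key, tuple) else key
        name = f"{goat}/L{key[1]}" if per_lactation else str(goat)
        out.append(ComponentSeries(
            goat_id=name, component=component,
            t=g["dim"].to_numpy(float), y=g[col].to_numpy(float)))
    return out
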