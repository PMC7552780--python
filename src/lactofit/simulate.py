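"""Seeded synthetic test-day herd generator.

Emulates the record structure of a small official-recording goat herd so
that every pipeline stage is testable without field data: first control on
average 21.21 +/- 13.71 days after kidding (truncated at >= 5), 4.80 +/-
2.86 controls per lactation (truncated at >= 2), roughly monthly spacing,
3.91 +/- 2.01 lactations per goat, lactation length 210-240 days.

Component values are a catalogue curve (per-goat parameters drawn around a
model's typical vector) times multiplicative noise — Gaussian factors for
the percentage traits, lognormal for somatic cell counts — with default
coefficients of variation 14.1, 21.7, 10.0, 6.6 and 148.7 % for protein,
fat, dry matter, lactose and SCC.  Multiplicative noise keeps the CV
constant along the lactation.  Ground-truth per-goat parameters are
returned (and written to a sidecar) for recovery tests.

Everything is driven by a single integer seed; the same seed reproduces the
same herd byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .catalogue import get_model
from .io import COMPONENT_COLUMNS

__all__ = ["HerdConfig", "generate_herd", "simulate_series", "mastitis_spike",
           "COMPONENT_LEVELS", "COMPONENT_CVS"]

# typical b0 magnitudes of the five components (%, %, %, %, cells/mL)
COMPONENT_LEVELS = {"protein": 4.0, "fat": 5.0, "dry_matter": 14.0,
                    "lactose": 5.0, "scc": 8.0e5}
# default per-component multiplicative-noise CVs (fractions)
COMPONENT_CVS = {"protein": 0.141, "fat": 0.217, "dry_matter": 0.100,
                 "lactose": 0.066, "scc": 1.487}
MILK_LEVEL_KG = 2.2  # daily yield scale for Murciano-Granadina-type goats
MILK_CV = 0.18


@dataclass(frozen=True)
class HerdConfig:
    """Study-condition parameters of the synthetic herd."""

    n_goats: int = 50
    lactations_mean: float = 3.91
    lactations_sd: float = 2.01
    first_control_mean: float = 21.21
    first_control_sd: float = 13.71
    first_control_min: float = 5.0
    controls_mean: float = 4.80
    controls_sd: float = 2.86
    controls_min: int = 2
    control_spacing: float = 30.0
    spacing_jitter: float = 4.0
    lactation_end: tuple = (210.0, 240.0)
    generating_model: str = "WOOD"
    param_cv: float = 0.05          # between-goat spread on each parameter
    param_corr: Optional[np.ndarray] = None  # optional correlation preset
    noise_cv: dict = field(default_factory=lambda: dict(COMPONENT_CVS))
    components: tuple = ("protein", "fat", "dry_matter", "lactose", "scc")
    seed: int = 0

    def __post_init__(self):
        if self.control_spacing >= self.lactation_end[0]:
            raise ValueError("control spacing exceeds lactation length")
        if self.n_goats < 1:
            raise ValueError("n_goats must be >= 1")


def _draw_params(rng, spec, level, cv, corr=None):
    base = np.asarray(spec.typical(level), dtype=float)
    k = len(base)
    if corr is not None:
        L = np.linalg.cholesky(corr[:k, :k])
        z = L @ rng.standard_normal(k)
    else:
        z = rng.standard_normal(k)
    return base * (1.0 + cv * z)


def simulate_series(model, params, n: int, cv: float, rng,
                    t_max: float = 210.0, *, lognormal: bool = False
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic series: n controls on [5, t_max], curve x noise."""
    spec = get_model(model) if isinstance(model, str) else model
    t = np.linspace(5.0, t_max, n)
    mu = spec(params, t)
    if cv <= 0:
        return t, mu
    if lognormal:
        sigma = np.sqrt(np.log1p(cv * cv))
        factor = rng.lognormal(-sigma * sigma / 2.0, sigma, size=n)
    else:
        factor = np.maximum(1.0 + cv * rng.standard_normal(n), 0.01)
    return t, mu * factor


def generate_herd(config: HerdConfig, *, out_csv=None, truth_csv=None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a test-day table and its ground-truth parameter sidecar.

    Returns (records, truth); ``records`` follows the data_io CSV schema,
    ``truth`` has one row per goat x component with the generating
    parameters.  Optional paths write both as CSV (fixed float format, so
    identical seeds give identical bytes).
    """
    rng = np.random.default_rng(config.seed)
    spec = get_model(config.generating_model)
    base_date = pd.Timestamp("2015-01-15")

    rows, truth_rows = [], []
    for gi in range(config.n_goats):
        goat = f"G{gi:04d}"
        # per-goat generating parameters, one draw per component
        goat_params = {}
        for comp in config.components:
            cv_between = config.param_cv * (2.0 if comp == "scc" else 1.0)
            goat_params[comp] = _draw_params(
                rng, spec, COMPONENT_LEVELS[comp], cv_between,
                config.param_corr)
            truth_rows.append({"goat_id": goat, "component": comp,
                               "model": spec.code,
                               **{f"b{j}": goat_params[comp][j]
                                  for j in range(spec.n_params)}})
        milk_params = _draw_params(rng, spec, MILK_LEVEL_KG, config.param_cv)

        n_lact = max(1, int(round(rng.normal(config.lactations_mean,
                                             config.lactations_sd))))
        kidding = base_date + pd.Timedelta(days=int(rng.integers(0, 365)))
        for lact in range(1, n_lact + 1):
            end = rng.uniform(*config.lactation_end)
            first = max(config.first_control_min,
                        rng.normal(config.first_control_mean,
                                   config.first_control_sd))
            n_controls = max(config.controls_min,
                             int(round(rng.normal(config.controls_mean,
                                                  config.controls_sd))))
            dims, d = [], first
            while len(dims) < n_controls and d <= end:
                dims.append(round(d))
                d += config.control_spacing + rng.uniform(
                    -config.spacing_jitter, config.spacing_jitter)
            dims = np.unique(np.asarray(dims, dtype=int))
            if len(dims) < 1:
                continue
            t = dims.astype(float)

            values = {}
            for comp in config.components:
                mu = spec(goat_params[comp], t)
                cv = config.noise_cv.get(comp, 0.0)
                if cv <= 0:
                    values[comp] = mu
                elif comp == "scc":
                    sigma = np.sqrt(np.log1p(cv * cv))
                    values[comp] = mu * rng.lognormal(
                        -sigma * sigma / 2.0, sigma, size=len(t))
                else:
                    values[comp] = mu * np.maximum(
                        1.0 + cv * rng.standard_normal(len(t)), 0.01)
            milk_mu = spec(milk_params, t)
            milk = milk_mu * np.maximum(
                1.0 + MILK_CV * rng.standard_normal(len(t)), 0.01)

            for j, dim in enumerate(dims):
                rows.append({
                    "goat_id": goat, "lactation_no": lact,
                    "kidding_date": kidding.date().isoformat(),
                    "control_date": (kidding + pd.Timedelta(days=int(dim))
                                     ).date().isoformat(),
                    "milk_kg": milk[j],
                    "protein_pct": values.get("protein", [np.nan] * len(t))[j],
                    "fat_pct": values.get("fat", [np.nan] * len(t))[j],
                    "dm_pct": values.get("dry_matter", [np.nan] * len(t))[j],
                    "lactose_pct": values.get("lactose", [np.nan] * len(t))[j],
                    "scc": values.get("scc", [np.nan] * len(t))[j],
                })
            # next lactation starts after this one ends plus a dry period
            kidding = kidding + pd.Timedelta(
                days=int(end) + int(rng.integers(30, 90)))

    records = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    if out_csv is not None:
        records.to_csv(out_csv, index=False, float_format="%.6f")
    if truth_csv is not None:
        truth.to_csv(truth_csv, index=False, float_format="%.10g")
    return records, truth


def mastitis_spike(series_df: pd.DataFrame, day: float, magnitude: float,
                   duration: float = 30.0) -> pd.DataFrame:
    """Scale SCC by ``magnitude`` over [day, day + duration].

    Emulates the transient somatic-cell surge around a clinical mastitis
    event (observed counts can approach 1e7 cells/mL).  Only the ``scc``
    column is touched; other components are left untouched.
    """
    if "scc" not in series_df.columns:
        raise ValueError("mastitis_spike requires an scc column")
    if "dim" in series_df.columns:
        dim = series_df["dim"].to_numpy(float)
    else:
        dim = (pd.to_datetime(series_df["control_date"])
               - pd.to_datetime(series_df["kidding_date"])).dt.days.to_numpy()
    if day > dim.max() or day + duration < dim.min():
        raise ValueError("spike window outside the series span")
    out = series_df.copy()
    mask = (dim >= day) & (dim <= day + duration)
    out.loc[mask, "scc"] = out.loc[mask, "scc"] * magnitude
    return out
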