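"""End-to-end driver: simulate/ingest -> standardize -> fit -> select ->
diagnose -> shape -> bayes, writing a reproducible artifact bundle.

The pipeline is a pure function of (input bytes, config, seed): rerunning
with the same configuration produces byte-identical CSV outputs.  Soft
failures (series that do not converge for a model) are data, recorded in
fits.csv; hard errors abort with the stage named.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bayes import complexity_anova
from .catalogue import REGISTRY
from .diagnostics import day_mean_residuals, durbin_watson, runs_test, \
    shapiro_francia
from .fitting import sweep
from .io import COMPONENTS, build_series, read_testday_table, \
    standardize_yields
from .selection import loocv_mmse, rank_models
from .shape import shape_report
from .simulate import HerdConfig, generate_herd

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)
_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_csv: Optional[str] = None          # or simulate with herd below
    herd: Optional[HerdConfig] = None
    components: Sequence[str] = COMPONENTS
    models: Optional[Sequence[str]] = None   # default: whole catalogue
    tol: float = 1e-8
    max_iter: int = 200
    per_lactation: bool = False
    persistency_method: str = "halfway_relative_rate"
    mmse: str = "top"                        # none | top | all
    mmse_top: int = 5
    out_dir: str = "lactofit_run"
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        herd = raw.pop("herd", None)
        cfg = cls(**raw)
        if herd is not None:
            cfg.herd = HerdConfig(**herd)
        return cfg


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if isinstance(o, HerdConfig):
            return {k: v for k, v in o.__dict__.items()
                    if not isinstance(v, np.ndarray)}
        return str(o)

    blob = json.dumps(cfg.__dict__, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a dict of output paths and key tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = list(config.models) if config.models else sorted(REGISTRY)

    # -- ingest ------------------------------------------------------------
    if config.input_csv is not None:
        try:
            table = read_testday_table(config.input_csv)
        except Exception as exc:
            raise PipelineError("ingest", str(exc)) from exc
    elif config.herd is not None:
        table, truth = generate_herd(config.herd)
        truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)
        table["kidding_date"] = pd.to_datetime(table["kidding_date"])
        table["control_date"] = pd.to_datetime(table["control_date"])
        table["dim"] = (table["control_date"] - table["kidding_date"]).dt.days
    else:
        raise PipelineError("ingest", "no input: set input_csv or herd")
    if table.empty:
        raise PipelineError("ingest", "empty test-day table")

    # -- standardize -------------------------------------------------------
    table = standardize_yields(table)
    table.assign(
        kidding_date=pd.to_datetime(table["kidding_date"]).dt.date,
        control_date=pd.to_datetime(table["control_date"]).dt.date,
    ).to_csv(out / "testday.csv", index=False, float_format=_FLOAT_FMT)

    # -- fit ---------------------------------------------------------------
    all_fits, series_by_key = [], {}
    for comp in config.components:
        series = build_series(table, comp, per_lactation=config.per_lactation)
        if not series:
            continue
        for s in series:
            series_by_key[(comp, s.goat_id)] = s
        sw = sweep(series, models, tol=config.tol, max_iter=config.max_iter)
        all_fits.append((comp, sw))
    if not all_fits:
        raise PipelineError("fit", "no fittable series")
    fits_frame = pd.concat([sw.to_frame() for _, sw in all_fits],
                           ignore_index=True)
    fits_frame.to_csv(out / "fits.csv", index=False, float_format=_FLOAT_FMT)
    conv = fits_frame[fits_frame["converged"]]
    logger.info("fit: %d/%d series x model fits converged",
                len(conv), len(fits_frame))
    for model, pct in (100.0 * fits_frame.groupby("model")["converged"]
                       .mean()).items():
        logger.info("fit: %-10s %5.1f%% fitted", model, pct)

    # -- select ------------------------------------------------------------
    reports = {}
    for comp, sw in all_fits:
        rep = rank_models(sw)
        if config.mmse != "none":
            chosen = (rep.index[:config.mmse_top] if config.mmse == "top"
                      else rep.index)
            mmse_vals = {}
            for m in chosen:
                vals = []
                for f in sw.fits:
                    if f.model == m and f.converged:
                        s = series_by_key[(comp, f.goat_id)]
                        v, _ = loocv_mmse(s, m, tol=config.tol,
                                          max_iter=config.max_iter)
                        if np.isfinite(v):
                            vals.append(v)
                if vals:
                    mmse_vals[m] = float(np.mean(vals))
            rep["mean_mmse"] = pd.Series(mmse_vals)
        rep["component"] = comp
        reports[comp] = rep
    criteria = pd.concat([r.reset_index() for r in reports.values()],
                         ignore_index=True)
    criteria.to_csv(out / "criteria.csv", index=False,
                    float_format=_FLOAT_FMT)

    # -- diagnose ----------------------------------------------------------
    diag_rows = []
    for comp, sw in all_fits:
        best = reports[comp].index[0]
        pairs = [(series_by_key[(comp, f.goat_id)].t, f.residuals)
                 for f in sw.fits
                 if f.model == best and f.converged and f.residuals is not None]
        if not pairs:
            continue
        day_series = day_mean_residuals(pairs)
        pooled = np.concatenate([np.asarray(r) for _, r in pairs])
        try:
            dw = durbin_watson(day_series.to_numpy())
        except ValueError:
            dw = np.nan
        rt = runs_test(day_series.to_numpy())
        sf = shapiro_francia(pooled) if len(pooled) >= 5 else None
        diag_rows.append({
            "component": comp, "model": best, "durbin_watson": dw,
            "runs_z": rt.statistic, "runs_p": rt.p_value,
            "sf_w": sf.statistic if sf else np.nan,
            "sf_p": sf.p_value if sf else np.nan,
            "n_days": len(day_series)})
    pd.DataFrame(diag_rows).to_csv(out / "diagnostics.csv", index=False,
                                   float_format=_FLOAT_FMT)

    # -- shape -------------------------------------------------------------
    shape_rows = []
    for comp, sw in all_fits:
        best = reports[comp].index[0]
        for f in sw.fits:
            if f.model != best or not f.converged:
                continue
            s = series_by_key[(comp, f.goat_id)]
            try:
                rep = shape_report(best, f.b, s.t,
                                   method=config.persistency_method)
            except ValueError:
                continue
            shape_rows.append({
                "component": comp, "goat_id": f.goat_id, "model": best,
                "t_peak": rep.t_peak, "y_peak": rep.y_peak,
                "persistency": rep.persistency,
                "persistency_method": rep.persistency_method,
                "change_per_event": rep.change_per_event,
                "method": rep.method})
    pd.DataFrame(shape_rows).to_csv(out / "shapes.csv", index=False,
                                    float_format=_FLOAT_FMT)

    # -- bayes -------------------------------------------------------------
    bayes_rows = []
    for comp, rep in reports.items():
        try:
            comparisons = complexity_anova(rep, seed=config.seed)
        except ValueError:
            continue
        for crit, cmp_ in comparisons.items():
            row = {"component": comp, "criterion": crit, "F": cmp_.F,
                   "p_value": cmp_.p_value, "bf10": cmp_.bf10,
                   "evidence": cmp_.evidence, "flagged": cmp_.flagged}
            for cls in cmp_.groups:
                row[f"post_mean_{cls}"] = cmp_.posterior_means[cls]
                lo, hi = cmp_.credible_intervals[cls]
                row[f"ci_{cls}"] = f"{lo:.4f}..{hi:.4f}"
            bayes_rows.append(row)
    pd.DataFrame(bayes_rows).to_csv(out / "bayes.csv", index=False,
                                    float_format=_FLOAT_FMT)

    # -- plots -------------------------------------------------------------
    if config.make_plots:
        _best_fit_plots(out, reports, all_fits, series_by_key)

    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": _config_hash(config),
                "models": models, "components": list(config.components)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {"out_dir": str(out), "criteria": criteria,
            "fits": fits_frame, "reports": reports}


def _best_fit_plots(out: Path, reports, all_fits, series_by_key) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .catalogue import get_model

    for comp, sw in all_fits:
        best = reports[comp].index[0]
        spec = get_model(best)
        fig, ax = plt.subplots(figsize=(6, 4))
        grid = np.linspace(1, 210, 300)
        shown = 0
        for f in sw.fits:
            if f.model != best or not f.converged or shown >= 12:
                continue
            s = series_by_key[(comp, f.goat_id)]
            ax.plot(s.t, s.y, ".", alpha=0.35, ms=4)
            with np.errstate(all="ignore"):
                ax.plot(grid, spec(f.b, grid), lw=0.8, alpha=0.7)
            shown += 1
        ax.set_xlabel("days in milk")
        ax.set_ylabel(comp)
        ax.set_title(f"{comp}: best-fitting model {best}")
        fig.tight_layout()
        fig.savefig(out / f"bestfit_{comp}.png", dpi=120)
        plt.close(fig)
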