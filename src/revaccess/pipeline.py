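"""End-to-end orchestration: simulate -> service areas -> interpolation ->
RAI -> Moran diagnostics -> screening -> model fits -> report.

One pipeline run analyses one city; each travel mode gets its own set of
access records and its own model fits (no pooling across modes). The
report mirrors the study's table layouts: a Moran table per mode, a model
table with OLS/SAR estimate-SE columns and GWR min-max columns, fit
statistics, and the AICc-based best-model flag (decisive only at a margin
of 3 or more).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import records_to_dataframe, write_access_records, write_city, write_service_areas
from .rai import build_access_records, network_distance_matrix
from .regression import (Design, GWRFit, ModelFit, SARFit, compare_models, fit_gwr,
                         fit_ols, fit_sar, pearson_screen, vif)
from .service_areas import city_service_areas
from .spatial import inverse_distance_weights, morans_i, residual_moran
from .surfaces import interpolate_all
from .synthetic import generate_city
from .types import CityBundle

log = logging.getLogger("revaccess.pipeline")

__all__ = ["run_pipeline", "render_tables", "Report", "fit_mode_models", "screen_covariates"]


@dataclass
class Report:
    """Per-mode Moran tables, retained covariates, VIF table, model fits."""

    seed: int
    modes: list[str]
    moran: dict[str, dict] = field(default_factory=dict)
    retained: dict[str, list[str]] = field(default_factory=dict)
    vif: dict[str, dict[str, float]] = field(default_factory=dict)
    models: dict[str, dict[str, dict]] = field(default_factory=dict)
    comparison: dict[str, dict] = field(default_factory=dict)
    n_outlets: int = 0

    def to_json(self) -> str:
        return json.dumps(_jsonable(self.__dict__), sort_keys=True, indent=1) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj


def _fit_payload(f: ModelFit) -> dict:
    out = {
        "names": f.names,
        "estimate": list(f.params),
        "std_estimate": list(f.std_params),
        "se": list(f.bse),
        "p": list(f.pvalues),
        "r2": f.r2, "adj_r2": f.adj_r2, "aicc": f.aicc, "loglik": f.loglik,
        "n": f.nobs,
    }
    if isinstance(f, SARFit):
        out["rho"] = f.rho
        out["rho_se"] = f.rho_se
    if isinstance(f, GWRFit):
        out["coef_min"] = list(f.coef_min)
        out["coef_max"] = list(f.coef_max)
        out["bandwidth"] = f.bandwidth
        out["trace_S"] = f.trace_S
    return out


def screen_covariates(frames: dict[str, pd.DataFrame], candidates: list[str],
                      alpha: float, harmonize: bool, vif_threshold: float,
                      ) -> tuple[dict[str, list[str]], dict[str, dict[str, float]]]:
    """Pearson screening per mode, optional cross-mode harmonization (the
    union of retained sets, so modes stay comparable), then an iterative
    VIF filter dropping the worst collinear covariate until all < threshold."""
    retained = {m: pearson_screen(df, "rai_sqrt", candidates, alpha=alpha)
                for m, df in frames.items()}
    if harmonize:
        union = sorted(set().union(*retained.values()))
        retained = {m: list(union) for m in retained}
    vifs: dict[str, dict[str, float]] = {}
    for m, df in frames.items():
        n = len(df)
        # a covariate can be (near-)constant in one mode even if it screened
        # in elsewhere (harmonization), e.g. when every bike service area
        # covers the whole city; such columns carry no information here
        keep = ["efo_type"]
        for c in retained[m]:
            if c == "efo_type":
                continue
            x = df[c].to_numpy(dtype=float)
            sd = x.std()
            if sd == 0 or sd < 1e-9 * max(1.0, abs(x.mean())):
                log.info("mode %s: dropping near-constant covariate %s", m, c)
                continue
            keep.append(c)
        # guard against overfitting: at most ~n/4 covariates, the strongest
        # outcome correlations first
        max_cov = max(2, n // 4)
        if len(keep) - 1 > max_cov:
            y = df["rai_sqrt"].to_numpy(dtype=float)
            strength = {c: abs(np.corrcoef(df[c].to_numpy(float), y)[0, 1])
                        for c in keep if c != "efo_type"}
            ranked = sorted(strength, key=lambda c: (-strength[c], c))
            keep = ["efo_type"] + sorted(ranked[:max_cov])
        while len(keep) >= 2:
            v = vif(df, keep)
            worst = max((name for name in keep if name != "efo_type"),
                        key=lambda nm: v[nm], default=None)
            if worst is not None and v[worst] >= vif_threshold:
                log.info("mode %s: dropping %s (VIF %.1f >= %.1f)", m, worst, v[worst],
                         vif_threshold)
                keep.remove(worst)
                continue
            # condition-number guard on the standardized design: VIF can
            # pass while the column set is still numerically fragile
            Z = df[keep].to_numpy(dtype=float)
            Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
            cond = np.linalg.cond(np.column_stack([np.ones(n), Z]))
            if cond > 1e8 and worst is not None:
                log.info("mode %s: dropping %s (condition number %.1e)", m, worst, cond)
                keep.remove(worst)
                continue
            vifs[m] = v
            break
        else:
            vifs[m] = {}
        retained[m] = [c for c in keep if c != "efo_type"]
    return retained, vifs


def fit_mode_models(df: pd.DataFrame, covariates: list[str], models: tuple[str, ...],
                    ) -> tuple[dict[str, ModelFit], dict]:
    """Fit the requested estimators on one mode's access records; residual
    Moran's I (inverse-Euclidean-distance weights on outlet points) is
    attached to each fit."""
    design = Design.from_dataframe(df, "rai_sqrt", ["efo_type"] + covariates,
                                   id_col="outlet_id")
    coords = df[["x", "y"]].to_numpy(dtype=float)
    weights = inverse_distance_weights(coords, ids=list(df["outlet_id"]))
    fits: dict[str, ModelFit] = {}
    if "ols" in models:
        fits["ols"] = fit_ols(design)
    if "sar" in models:
        fits["sar"] = fit_sar(design, weights)
    if "gwr" in models:
        fits["gwr"] = fit_gwr(design, coords)
    payload = {}
    for name, f in fits.items():
        entry = _fit_payload(f)
        try:
            rm = residual_moran(f.residuals, weights)
            entry["residual_moran"] = {"I": rm.I, "z": rm.z_score, "p": rm.p_value}
        except ValueError:
            entry["residual_moran"] = None
        payload[name] = entry
    return fits, payload


def run_pipeline(config: PipelineConfig, city: CityBundle | None = None,
                 write_outputs: bool = True) -> Report:
    """Run every stage on one (generated or supplied) city; deterministic
    under the config seed."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    city_cfg = config.city
    if config.seed is not None:
        from dataclasses import replace
        city_cfg = replace(city_cfg, seed=config.seed)
    if city is None:
        log.info("generating synthetic city (seed=%d)", city_cfg.seed)
        city = generate_city(city_cfg)
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        write_city(city, outdir / "city")

    log.info("city: %d outlets, %d zones, %d network nodes",
             len(city.outlets), len(city.zones), len(city.network))
    dmat = network_distance_matrix(city.outlets, city.network)

    report = Report(seed=city_cfg.seed, modes=list(config.modes),
                    n_outlets=len(city.outlets))
    frames: dict[str, pd.DataFrame] = {}
    for mode in config.modes:
        areas = city_service_areas(city, mode)
        log.info("mode %s: %d service areas", mode, len(areas))
        cov_rows = interpolate_all(city.zones, areas)
        records = build_access_records(city, areas, cov_rows, dmatrix=dmat,
                                       config=config.rai)
        df = records_to_dataframe(records)
        frames[mode] = df
        if write_outputs:
            write_service_areas(areas, outdir / f"areas_{mode}.geojson")
            write_access_records(records, outdir / f"access_{mode}.csv")
        pts = df[["x", "y"]].to_numpy(dtype=float)
        w = inverse_distance_weights(pts)
        try:
            mi = morans_i(df["rai_sqrt"].to_numpy(), w)
            report.moran[mode] = {"I": mi.I, "expected_I": mi.expected_I,
                                  "z": mi.z_score, "p": mi.p_value, "n": mi.n}
        except ValueError as exc:
            report.moran[mode] = {"error": str(exc)}

    candidates = [c for c in city.covariate_names]
    retained, vifs = screen_covariates(frames, candidates, config.screening_alpha,
                                       config.harmonize_screening, config.vif_threshold)
    report.retained = retained
    report.vif = vifs

    for mode in config.modes:
        fits, payload = fit_mode_models(frames[mode], retained[mode], config.models)
        report.models[mode] = payload
        if len(fits) >= 2:
            report.comparison[mode] = compare_models(fits)

    if write_outputs:
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(render_tables(report))
        log.info("report written to %s", outdir)
    return report


# ---------------------------------------------------------------------------
# Text rendering


def _fmt(v, nd=3) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "-"
    return f"{v:.{nd}f}"


def _star(p) -> str:
    if p is None:
        return ""
    return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


def render_tables(report: Report) -> str:
    """Human-readable tables mirroring the study layout: Moran block, then
    per-mode model tables (estimate/SE for OLS and SAR; min/max for GWR),
    fit statistics and footnotes. Relationships that are not significant
    at the 10% level render as '-'."""
    out = []
    out.append("Moran's I of sqrt(RAI) per travel mode")
    out.append(f"{'statistic':<14}" + "".join(f"{m:>12}" for m in report.modes))
    for stat, key in [("Moran's I", "I"), ("Expected I", "expected_I"),
                      ("z-score", "z"), ("p-value", "p")]:
        row = [f"{stat:<14}"]
        for m in report.modes:
            cell = report.moran.get(m, {})
            row.append(f"{_fmt(cell.get(key)):>12}")
        out.append("".join(row))
    out.append("")

    for mode in report.modes:
        models = report.models.get(mode, {})
        if not models:
            log.info("mode %s: no fitted models; table omitted", mode)
            continue
        out.append(f"=== {mode} zone models (n = {models[next(iter(models))]['n']}) ===")
        names = models.get("ols", models[next(iter(models))])["names"]
        header = f"{'variable':<26}"
        for m in ("ols", "sar"):
            if m in models:
                header += f"{m.upper() + ' est':>14}{'SE':>10}"
        if "gwr" in models:
            header += f"{'GWR min':>12}{'GWR max':>12}"
        out.append(header)
        for j, nm in enumerate(names):
            row = f"{nm:<26}"
            for m in ("ols", "sar"):
                if m not in models:
                    continue
                fm = models[m]
                try:
                    jj = fm["names"].index(nm)
                except ValueError:
                    row += f"{'-':>14}{'-':>10}"
                    continue
                p = fm["p"][jj]
                if nm != "intercept" and (p is None or p >= 0.1):
                    row += f"{'-':>14}{'-':>10}"
                else:
                    row += f"{_fmt(fm['estimate'][jj]) + _star(p):>14}{_fmt(fm['se'][jj]):>10}"
            if "gwr" in models:
                fg = models["gwr"]
                try:
                    jj = fg["names"].index(nm)
                    row += f"{_fmt(fg['coef_min'][jj]):>12}{_fmt(fg['coef_max'][jj]):>12}"
                except ValueError:
                    row += f"{'-':>12}{'-':>12}"
            out.append(row)
        out.append("Fit statistics")
        for stat, key in [("R2", "r2"), ("Adj. R2", "adj_r2"), ("AICc", "aicc"),
                          ("rho", "rho")]:
            row = f"{stat:<26}"
            for m in ("ols", "sar", "gwr"):
                if m in models:
                    row += f"{_fmt(models[m].get(key)):>14}"
            out.append(row)
        row = f"{'residual Moran I':<26}"
        for m in ("ols", "sar", "gwr"):
            if m in models:
                rm = models[m].get("residual_moran")
                row += f"{_fmt(rm['I'] if rm else None):>14}"
        out.append(row)
        cmp_ = report.comparison.get(mode)
        if cmp_:
            flag = "decisively best" if cmp_["decisive"] else "best (not decisive)"
            out.append(f"model selection: {cmp_['best']} {flag} "
                       f"(AICc margin {cmp_['margin']:.2f})")
        out.append("")
    out.append("Spatial relationships conceptualized using inverse Euclidean distance; "
               "* p < 0.1; ** p < 0.05; *** p < 0.01; -, no statistically "
               "significant relationship.")
    return "\n".join(out) + "\n"
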