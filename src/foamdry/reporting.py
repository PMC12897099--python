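"""Pipeline composition and tabular report assembly.

`run_full_pipeline` chains the stages — synthetic (or file-based) weighing
series, reduction to moisture ratio, seven-model fitting and selection,
slope-method diffusivity, Arrhenius regression, colour derivation and the
temperature recommendation — and collects everything into delimited-text
tables mirroring the layout of a drying-kinetics study report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference as ref
from .color import browning_index_summary, chroma, hue_angle
from .diffusivity import ArrheniusFit, DiffusivityEstimate, arrhenius_fit, estimate_Deff
from .drying import DryingRun, build_drying_run
from .fitting import FitConfig, FitResult, fit_all_models, select_model
from .response import TemperatureRecommendation, fit_response, recommend_temperature
from .synthetic import SyntheticConfig, generate_run

logger = logging.getLogger(__name__)

#: Desirability direction per quality parameter (colour coordinates are
#: steered toward the fresh-pulp value).
DEFAULT_DIRECTIONS: dict[str, str] = {
    "moisture_wb": "minimize",
    "ash": "maximize",
    "tta": "maximize",
    "rs": "maximize",
    "vc": "maximize",
    "tc": "maximize",
}


@dataclass
class AnalysisReport:
    """Collected tables of one full pipeline run."""

    fit_table: pd.DataFrame | None = None          # per temperature x model
    selection: dict[float, str] = field(default_factory=dict)
    diffusivity_table: pd.DataFrame | None = None
    arrhenius: ArrheniusFit | None = None
    color_table: pd.DataFrame | None = None
    quality_models: pd.DataFrame | None = None
    recommendation: TemperatureRecommendation | None = None
    settings: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Write every table as CSV (4-decimal display copies alongside)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in [
            ("fit_table", self.fit_table),
            ("diffusivity", self.diffusivity_table),
            ("color", self.color_table),
            ("quality_models", self.quality_models),
        ]:
            if df is not None:
                df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
        summary = {}
        if self.arrhenius is not None:
            summary.update(
                Ea_kJ_mol=round(self.arrhenius.Ea_kJ_mol, 4),
                D0_m2_s=self.arrhenius.D0,
                arrhenius_r2=round(self.arrhenius.r2, 4),
            )
        if self.recommendation is not None:
            summary.update(
                mean_optimum_C=round(self.recommendation.mean_optimum, 4),
                recommended_T_C=self.recommendation.grid_choice,
            )
        if summary:
            pd.Series(summary).to_csv(outdir / "summary.csv", header=False)


def fit_table_row(temperature: float, fit: FitResult) -> dict:
    row = {"temperature_C": temperature, "model": fit.model_name}
    for p in ("a", "n", "k", "b"):
        row[p] = fit.params.get(p, np.nan)
    row.update(R2=fit.R2, MRE=fit.MRE, SDE=fit.SDE, DF=fit.DF,
               converged=fit.converged)
    return row


def kinetics_report(
    runs: dict[float, DryingRun], config: FitConfig | None = None
) -> tuple[pd.DataFrame, dict[float, str], dict[float, list[FitResult]]]:
    """Fit the whole bank to each run; return the table and winners."""
    rows, winners, fits_by_T = [], {}, {}
    for T, run in sorted(runs.items()):
        fits = fit_all_models(run, config=config)
        fits_by_T[T] = fits
        sel = select_model(fits)
        winners[T] = sel.winner.model_name
        rows.extend(fit_table_row(T, f) for f in fits)
    return pd.DataFrame(rows), winners, fits_by_T


def color_report(color_replicates: pd.DataFrame) -> pd.DataFrame:
    """Per-sample colour table: mean L, a, b with derived C*, h*, BI.

    BI is computed both on the replicate means and as the mean of
    per-replicate BIs; the table reports both.
    """
    rows = []
    for sample, grp in color_replicates.groupby("sample", sort=False):
        L, a, b = (grp[c].to_numpy(float) for c in ("L", "a", "b"))
        bi = browning_index_summary(L, a, b)
        rows.append({
            "sample": sample,
            "L": L.mean(), "a": a.mean(), "b": b.mean(),
            "C": chroma(a.mean(), b.mean()),
            "h": hue_angle(a.mean(), b.mean()),
            "BI_of_means": bi["bi_of_means"],
            "mean_of_BIs": bi["mean_of_bis"],
        })
    return pd.DataFrame(rows)


def run_full_pipeline(
    synthetic_config: SyntheticConfig | None = None,
    fit_config: FitConfig | None = None,
    thickness_m: float = 0.015,
    quality_replicates: pd.DataFrame | None = None,
    color_replicates: pd.DataFrame | None = None,
    directions: dict[str, str] | None = None,
) -> AnalysisReport:
    """Run every stage on synthetic (or supplied) data; deterministic per seed."""
    from .synthetic import generate_quality_tables

    synthetic_config = synthetic_config or SyntheticConfig()
    report = AnalysisReport()
    report.settings = {
        "seed": synthetic_config.seed,
        "noise_sd": synthetic_config.noise_sd,
        "thickness_m": thickness_m,
        "time_unit": "min (kinetics), s (diffusivity)",
    }

    runs = {}
    for T in sorted(synthetic_config.params_by_temp):
        series, _ = generate_run(synthetic_config, T)
        runs[T] = build_drying_run(series, synthetic_config.dry_mass)

    report.fit_table, report.selection, _ = kinetics_report(runs, fit_config)

    estimates = [estimate_Deff(run, L=thickness_m) for _, run in sorted(runs.items())]
    report.diffusivity_table = pd.DataFrame(
        {
            "temperature_C": [e.temperature_C for e in estimates],
            "deff_m2s": [e.Deff for e in estimates],
            "r2_loglinear": [e.r2_loglinear for e in estimates],
            "n_points": [e.n_points_used for e in estimates],
        }
    )
    report.arrhenius = arrhenius_fit(estimates)

    if quality_replicates is None or color_replicates is None:
        tables = generate_quality_tables(seed=synthetic_config.seed)
        if quality_replicates is None:
            quality_replicates = tables["quality"]
        if color_replicates is None:
            color_replicates = tables["color"]
    report.color_table = color_report(color_replicates)

    directions = directions or DEFAULT_DIRECTIONS
    models = []
    for param, direction in directions.items():
        sub = quality_replicates[
            (quality_replicates["parameter"] == param)
            & (quality_replicates["sample"] != "pulp")
        ]
        if sub.empty:
            continue
        models.append(
            fit_response(
                param,
                sub["sample"].to_numpy(float),
                sub["value"].to_numpy(float),
                direction=direction,
            )
        )
    if models:
        report.quality_models = pd.DataFrame(
            {
                "parameter": [m.parameter_name for m in models],
                "degree": [m.degree for m in models],
                "coefficients": [list(np.round(m.coefficients, 6)) for m in models],
                "R2": [m.R2 for m in models],
                "optimum_T": [m.optimum_T for m in models],
                "optimum_kind": [m.optimum_kind for m in models],
            }
        )
        report.recommendation = recommend_temperature(models)
    return report
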