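"""One-call analysis pipeline: fit every response, test model adequacy,
optimize overall desirability, and compare predictions with verification
runs.

The report bundle is a plain dict of JSON-serializable values plus the
underlying fit objects, so it can be written to disk deterministically
(no timestamps) and re-read by downstream tooling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix
from . import rsm
from .desirability import (
    DesirabilitySpec,
    OptimizationResult,
    default_anchors,
    optimize_desirability,
)
from .validation import fold_range, validate_predictions

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings for a full design-to-optimum analysis.

    responses : subset of response-table columns to analyse (default all).
    anchors : desirability overrides; by default each response gets a
        maximize goal anchored at its observed min/max with a linear ramp.
    grid_step : coded spacing of the desirability grid search.
    alpha : significance level for model/effect/lack-of-fit tests.
    cv_limit : observed-vs-predicted CV (%) below which a verification run
        counts as agreeing with the model.
    """

    responses: list[str] | None = None
    anchors: DesirabilitySpec | None = None
    grid_step: float = 0.02
    alpha: float = 0.05
    cv_limit: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, with a JSON-friendly summary."""

    fits: dict[str, rsm.QuadraticFit]
    anova_tables: dict[str, pd.DataFrame]
    effects: dict[str, pd.DataFrame]
    optimization: OptimizationResult
    validation: pd.DataFrame | None
    fold_ranges: dict[str, float]
    summary: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary, indent=2, sort_keys=True, **kwargs)


def run_full_analysis(
    design: DesignMatrix,
    responses: pd.DataFrame,
    config: AnalysisConfig | None = None,
    observed_optimum: dict[str, float] | None = None,
) -> AnalysisReport:
    """Run the whole chain: OLS fits, ANOVA, effects, desirability, validation.

    Parameters
    ----------
    design : DesignMatrix
        The experimental design.
    responses : DataFrame
        One column per response, indexed by run_id (or aligned by position).
    config : AnalysisConfig, optional
    observed_optimum : {response: measured value}, optional
        Verification measurements at the optimum; enables the
        observed-vs-predicted CV table.
    """
    config = config or AnalysisConfig()
    names = config.responses or list(responses.columns)
    missing = set(names) - set(responses.columns)
    if missing:
        raise KeyError(f"responses not in table: {sorted(missing)}")

    fits: dict[str, rsm.QuadraticFit] = {}
    anovas: dict[str, pd.DataFrame] = {}
    effects: dict[str, pd.DataFrame] = {}
    for name in names:
        logger.info("fitting quadratic model for %s", name)
        fit = rsm.fit_quadratic(design, responses[name], response_name=name)
        fits[name] = fit
        anovas[name] = rsm.anova(fit, design)
        effects[name] = rsm.standardized_effects(fit, alpha=config.alpha)

    spec = config.anchors or default_anchors(responses[names])
    logger.info("optimizing overall desirability over %d responses", len(names))
    opt = optimize_desirability(
        fits, spec, design=design, step=config.grid_step
    )

    folds = {
        name: fold_range(responses[name].to_numpy())
        for name in names
        if (responses[name] > 0).all()
    }

    validation = None
    if observed_optimum is not None:
        validation = validate_predictions(
            observed_optimum,
            {k: opt.predicted[k] for k in observed_optimum},
            cv_limit=config.cv_limit,
        )

    f_crit = rsm.critical_f(
        fits[names[0]].df_model, fits[names[0]].df_residual, config.alpha
    )
    summary = {
        "responses": names,
        "model": {
            name: {
                "r_squared": fits[name].r_squared,
                "F_model": float(anovas[name].loc["model", "F"]),
                "df": [fits[name].df_model, fits[name].df_residual],
                "p_model": float(anovas[name].loc["model", "p"]),
                "F_lack_of_fit": _maybe(anovas[name].loc["lack_of_fit", "F"]),
                "p_lack_of_fit": _maybe(anovas[name].loc["lack_of_fit", "p"]),
                "lack_of_fit_significant": _lof_flag(
                    anovas[name].loc["lack_of_fit", "p"], config.alpha
                ),
            }
            for name in names
        },
        "critical_F": f_crit,
        "fold_ranges": folds,
        "optimum": {
            "coded": [float(v) for v in opt.coded_optimum],
            "real": [float(v) for v in opt.real_optimum],
            "real_rounded": opt.real_rounded(),
            "factors": opt.factor_names,
            "predicted": opt.predicted,
            "d": opt.d,
            "D": opt.D,
        },
    }
    if validation is not None:
        summary["validation"] = {
            name: {
                "observed": float(row["observed"]),
                "predicted": float(row["predicted"]),
                "cv_percent": float(row["cv_percent"]),
                "within_limit": bool(row["within_limit"]),
            }
            for name, row in validation.iterrows()
        }
    return AnalysisReport(
        fits=fits,
        anova_tables=anovas,
        effects=effects,
        optimization=opt,
        validation=validation,
        fold_ranges=folds,
        summary=summary,
    )


def _maybe(x) -> float | None:
    return None if pd.isna(x) else float(x)


def _lof_flag(p, alpha: float) -> bool | None:
    if pd.isna(p):
        return None
    return bool(p <= alpha)


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """Write the JSON summary and companion CSVs; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "analysis_report.json"
    json_path.write_text(report.to_json())
    for name, fit in report.fits.items():
        fit.coef_table().to_csv(out / f"coefficients_{name}.csv")
        report.anova_tables[name].to_csv(out / f"anova_{name}.csv")
        report.effects[name].to_csv(out / f"effects_{name}.csv")
    report.optimization.profiles.to_csv(out / "desirability_profiles.csv", index=False)
    if report.validation is not None:
        report.validation.to_csv(out / "validation.csv")
    return json_path
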