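"""Second-order response-surface fitting, ANOVA and standardized effects.

Each response is modelled by the full quadratic polynomial in the coded
factors,

    y = b0 + sum_i bi xi + sum_i bii xi^2 + sum_{i<j} bij xi xj + e,

fit by ordinary least squares.  The ANOVA partitions the total sum of
squares into model and residual parts, and — when the design carries
replicated runs — further splits the residual into lack-of-fit and pure
error, giving the classical adequacy test for the quadratic surface.
Standardized effects (t = beta / se) are the numeric content of a Pareto
chart of effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignMatrix

__all__ = [
    "QuadraticFit",
    "SingularDesignError",
    "UnderdeterminedError",
    "quadratic_terms",
    "model_matrix",
    "fit_quadratic",
    "anova",
    "critical_f",
    "standardized_effects",
    "predict",
    "response_surface_grid",
]

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """Model matrix is rank deficient for the requested quadratic."""


class UnderdeterminedError(ValueError):
    """Fewer runs than model terms."""


def quadratic_terms(factor_names: list[str]) -> list[str]:
    """Canonical term order: intercept, linear, quadratic, interactions."""
    names = list(factor_names)
    terms = ["intercept"]
    terms += names
    terms += [f"{n}^2" for n in names]
    terms += [
        f"{a}:{b}" for i, a in enumerate(names) for b in names[i + 1 :]
    ]
    return terms


def model_matrix(coded_points: np.ndarray, k: int | None = None) -> np.ndarray:
    """Full second-order model matrix for coded points (n, k) -> (n, p)."""
    pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
    if k is not None and pts.shape[1] != k:
        raise ValueError(f"expected {k} coordinates, got {pts.shape[1]}")
    n, k = pts.shape
    cols = [np.ones(n)]
    cols += [pts[:, j] for j in range(k)]
    cols += [pts[:, j] ** 2 for j in range(k)]
    cols += [
        pts[:, i] * pts[:, j] for i in range(k) for j in range(i + 1, k)
    ]
    return np.column_stack(cols)


@dataclass
class QuadraticFit:
    """OLS fit of the full quadratic to one response channel."""

    response_name: str
    factor_names: list[str]
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    observed: np.ndarray
    r_squared: float
    df_model: int
    df_residual: int
    mse_residual: float

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def coef_table(self) -> pd.DataFrame:
        """Coefficients with standard errors, t and two-sided p values."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.beta / self.se
        p = 2 * stats.t.sf(np.abs(t), self.df_residual)
        return pd.DataFrame(
            {"term": self.terms, "beta": self.beta, "se": self.se, "t": t, "p": p}
        ).set_index("term")


def _response_vector(response, design: DesignMatrix) -> np.ndarray:
    """Accept a pandas Series (aligned by run_id when possible) or array."""
    if isinstance(response, pd.Series):
        if response.index.is_unique and set(design.run_ids) <= set(response.index):
            return response.loc[design.run_ids].to_numpy(dtype=float)
        return response.to_numpy(dtype=float)
    return np.asarray(response, dtype=float)


def fit_quadratic(
    design: DesignMatrix, response, response_name: str | None = None
) -> QuadraticFit:
    """Fit the full second-order polynomial to one response by OLS.

    Parameters
    ----------
    design : DesignMatrix
        The experimental design; fitting uses its coded levels.
    response : array-like or pandas Series
        One observation per run.  A Series whose index contains the design's
        run_ids is aligned by run_id, so row order need not match.
    response_name : str, optional
        Label carried into reports; defaults to the Series name or ``"y"``.

    Returns
    -------
    QuadraticFit
        Coefficients on the coded scale, standard errors from the residual
        mean square, residuals, and R².
    """
    if response_name is None:
        response_name = getattr(response, "name", None) or "y"
    y = _response_vector(response, design)
    X = model_matrix(design.coded)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"response has {y.shape[0]} values for {n} runs")
    if n <= p:
        raise UnderdeterminedError(
            f"{n} runs cannot identify {p} model terms plus error"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(
            "model matrix is rank deficient; the design does not support the "
            "full quadratic"
        )
    res = sm.OLS(y, X).fit()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a constant response is fit exactly by the intercept: define R^2 = 1
    r2 = 1.0 if ss_tot == 0.0 else float(res.rsquared)
    return QuadraticFit(
        response_name=response_name,
        factor_names=[f.name for f in design.factors],
        terms=quadratic_terms([f.name for f in design.factors]),
        beta=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        observed=y,
        r_squared=r2,
        df_model=int(res.df_model),
        df_residual=int(res.df_resid),
        mse_residual=float(res.mse_resid),
    )


def predict(fit: QuadraticFit, coded_point: np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted quadratic at one or more coded points.

    Extrapolation outside the usual coded design region is permitted but
    logged, since the quadratic has no validity claim out there.
    """
    pts = np.atleast_2d(np.asarray(coded_point, dtype=float))
    out = model_matrix(pts, k=fit.k) @ fit.beta
    limit = (2.0**fit.k) ** 0.25 + 1e-9
    if np.any(np.abs(pts) > limit):
        logger.warning(
            "prediction at coded point beyond |%.3f|: extrapolating outside "
            "the design region",
            limit,
        )
    if np.ndim(coded_point) == 1:
        return float(out[0])
    return out


def anova(fit: QuadraticFit, design: DesignMatrix, response=None) -> pd.DataFrame:
    """ANOVA for a quadratic fit, with a lack-of-fit / pure-error split.

    Pure error is the within-group sum of squares over replicated runs
    (runs with identical coded coordinates — for a CCD, the center
    replicates); lack of fit is the remaining residual variation.  With
    fewer than two replicate runs the lack-of-fit rows are returned as NaN
    and the whole-model F is still reported.

    Returns
    -------
    pandas.DataFrame
        Rows ``model, residual, lack_of_fit, pure_error, total`` with
        columns SS, df, MS, F, p.
    """
    y = fit.observed if response is None else _response_vector(response, design)
    ss_res = float(np.sum(fit.residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_mod = ss_tot - ss_res
    df_mod, df_res = fit.df_model, fit.df_residual

    ms_mod = ss_mod / df_mod
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    if ss_tot == 0.0:
        f_mod, p_mod = 0.0, 1.0
    else:
        f_mod = ms_mod / ms_res if ms_res > 0 else np.inf
        p_mod = float(stats.f.sf(f_mod, df_mod, df_res))

    # replicate groups: runs sharing identical coded coordinates
    coded = np.round(design.coded, 12)
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(map(tuple, coded)):
        groups.setdefault(row, []).append(i)
    ss_pe = 0.0
    df_pe = 0
    for idx in groups.values():
        if len(idx) > 1:
            vals = y[idx]
            ss_pe += float(np.sum((vals - vals.mean()) ** 2))
            df_pe += len(idx) - 1

    if df_pe >= 1 and df_res - df_pe >= 1:
        df_lof = df_res - df_pe
        ss_lof = ss_res - ss_pe
        ms_pe = ss_pe / df_pe
        ms_lof = ss_lof / df_lof
        if ms_pe > 0:
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = np.inf, 0.0
        lof_row = [ss_lof, df_lof, ms_lof, f_lof, p_lof]
        pe_row = [ss_pe, df_pe, ms_pe, np.nan, np.nan]
    else:
        lof_row = [np.nan] * 5
        pe_row = [np.nan] * 5

    table = pd.DataFrame(
        [
            [ss_mod, df_mod, ms_mod, f_mod, p_mod],
            [ss_res, df_res, ms_res, np.nan, np.nan],
            lof_row,
            pe_row,
            [ss_tot, df_mod + df_res, np.nan, np.nan, np.nan],
        ],
        index=["model", "residual", "lack_of_fit", "pure_error", "total"],
        columns=["SS", "df", "MS", "F", "p"],
    )
    return table


def critical_f(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-``alpha`` quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.f.ppf(1 - alpha, df1, df2))


def standardized_effects(fit: QuadraticFit, alpha: float = 0.05) -> pd.DataFrame:
    """Standardized effects t = beta/se for all non-intercept terms.

    Sorted by |t| descending (ties broken by canonical term order), with a
    two-sided significance flag against t(df_residual).  This table is the
    numeric content of a Pareto chart of effects.  If the fit has zero
    residual variance all |t| are infinite and flagged.
    """
    if fit.df_residual < 1:
        raise ValueError("standardized effects require df_residual >= 1")
    tab = fit.coef_table().drop(index="intercept")
    if not np.all(np.isfinite(tab["t"])):
        warnings.warn(
            "zero residual variance: standardized effects are infinite",
            RuntimeWarning,
            stacklevel=2,
        )
    t_crit = stats.t.ppf(1 - alpha / 2, fit.df_residual)
    tab = tab.assign(significant=np.abs(tab["t"]) >= t_crit)
    order = np.argsort(-np.abs(tab["t"].to_numpy()), kind="stable")
    return tab.iloc[order]


def response_surface_grid(
    fit: QuadraticFit,
    vary: tuple[int, int],
    fixed: np.ndarray | dict[int, float] | None = None,
    resolution: int = 41,
    bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Predictions over a rectangular coded grid in two factors.

    Parameters
    ----------
    vary : (int, int)
        Indices of the two factors swept over the grid; must differ.
    fixed : array or {index: level}, optional
        Coded levels of the remaining factors (default 0, the center).
    resolution : int
        Nodes per axis (>= 2).
    bounds : (low, high), optional
        Coded interval per axis; defaults to ±alpha of a rotatable design.

    Returns
    -------
    pandas.DataFrame
        Long format with the two varied factors' coded levels and the
        prediction, ``resolution**2`` rows.
    """
    i, j = vary
    if i == j:
        raise ValueError("vary indices must name two different factors")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if bounds is None:
        a = (2.0**fit.k) ** 0.25
        bounds = (-a, a)
    base = np.zeros(fit.k)
    if fixed is not None:
        if isinstance(fixed, dict):
            for idx, lev in fixed.items():
                base[idx] = lev
        else:
            fixed = np.asarray(fixed, dtype=float)
            others = [m for m in range(fit.k) if m not in (i, j)]
            if fixed.shape == (fit.k,):
                base = fixed.copy()
            elif fixed.shape == (len(others),):
                base[others] = fixed
            else:
                raise ValueError("fixed levels have the wrong length")
    axis = np.linspace(bounds[0], bounds[1], resolution)
    gi, gj = np.meshgrid(axis, axis, indexing="ij")
    pts = np.tile(base, (resolution**2, 1))
    pts[:, i] = gi.ravel()
    pts[:, j] = gj.ravel()
    preds = model_matrix(pts, k=fit.k) @ fit.beta
    return pd.DataFrame(
        {
            fit.factor_names[i]: pts[:, i],
            fit.factor_names[j]: pts[:, j],
            "predicted": preds,
        }
    )
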