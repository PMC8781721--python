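"""Desirability-function multi-response optimization.

Each fitted response y is mapped to an individual desirability d in [0, 1]
between two anchors L (worthless, d = 0) and H (fully desirable, d = 1),
with a power ``s`` shaping the ramp; the overall desirability D is the
geometric mean of the individual d's.  Maximizing D over the experimental
region yields a single compromise factor setting — the standard Derringer–
Suich approach to simultaneous optimization of several responses.

The optimizer is an exhaustive vectorized grid search over the coded region
followed by a shrinking-step coordinate polish, which is robust for the
smooth low-dimensional surfaces a central composite design produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .rsm import QuadraticFit, model_matrix

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "OptimizationResult",
    "InvalidSpecError",
    "individual_desirability",
    "overall_desirability",
    "default_anchors",
    "optimize_desirability",
]


class InvalidSpecError(ValueError):
    """Raised for inconsistent desirability settings."""


@dataclass(frozen=True)
class ResponseGoal:
    """Desirability settings for one response.

    goal : 'maximize', 'minimize' or 'target'
    L, H : anchors in response units (H > L).  For 'maximize', d ramps from
        0 at L to 1 at H; for 'minimize' the ramp is mirrored; for 'target'
        d peaks at ``target`` and falls to 0 at both anchors.
    s : ramp exponent (> 0); 1 is linear.
    target : required for goal='target'; must lie inside (L, H).
    """

    goal: str = "maximize"
    L: float = 0.0
    H: float = 1.0
    s: float = 1.0
    target: float | None = None

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target"):
            raise InvalidSpecError(f"unknown goal {self.goal!r}")
        if not self.H > self.L:
            raise InvalidSpecError(f"anchors require H > L, got L={self.L}, H={self.H}")
        if not self.s > 0:
            raise InvalidSpecError("shape exponent s must be > 0")
        if self.goal == "target":
            if self.target is None or not self.L < self.target < self.H:
                raise InvalidSpecError("'target' goal needs L < target < H")


#: Mapping from response name to its goal.
DesirabilitySpec = dict[str, ResponseGoal]


def individual_desirability(y, goal: ResponseGoal) -> np.ndarray | float:
    """Map predicted response value(s) to desirability in [0, 1]."""
    y = np.asarray(y, dtype=float)
    L, H, s = goal.L, goal.H, goal.s
    if goal.goal == "maximize":
        d = np.clip((y - L) / (H - L), 0.0, 1.0) ** s
    elif goal.goal == "minimize":
        d = np.clip((H - y) / (H - L), 0.0, 1.0) ** s
    else:  # target
        T = goal.target
        left = np.clip((y - L) / (T - L), 0.0, 1.0)
        right = np.clip((H - y) / (H - T), 0.0, 1.0)
        d = np.where(y <= T, left, right) ** s
    if d.ndim == 0:
        return float(d)
    return d


def overall_desirability(d) -> float:
    """Geometric mean of individual desirabilities; 0 annihilates."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise InvalidSpecError("overall desirability of an empty vector")
    if np.any((d < 0) | (d > 1)):
        raise InvalidSpecError("individual desirabilities must lie in [0, 1]")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(d))))


def default_anchors(responses: pd.DataFrame, s: float = 1.0) -> DesirabilitySpec:
    """Maximize-goals anchored at each response's observed min and max.

    This is the convention of a desirability profiler run with no user
    overrides: the worst observed value of a response is worthless, the
    best fully desirable, with a linear ramp between.
    """
    spec: DesirabilitySpec = {}
    for name in responses.columns:
        col = responses[name].to_numpy(dtype=float)
        lo, hi = float(np.min(col)), float(np.max(col))
        if not hi > lo:
            raise InvalidSpecError(
                f"response {name!r} is constant; anchors are undefined"
            )
        spec[name] = ResponseGoal(goal="maximize", L=lo, H=hi, s=s)
    return spec


@dataclass
class OptimizationResult:
    """Argmax of the overall desirability over the search region."""

    coded_optimum: np.ndarray
    real_optimum: np.ndarray
    factor_names: list[str]
    predicted: dict[str, float]
    d: dict[str, float]
    D: float
    profiles: pd.DataFrame
    region: tuple[np.ndarray, np.ndarray]

    def real_rounded(self) -> dict[str, int]:
        """Real-unit optimum rounded to integers, reporting convention."""
        return {
            n: int(round(v)) for n, v in zip(self.factor_names, self.real_optimum)
        }


def _d_matrix(
    fits: dict[str, QuadraticFit], spec: DesirabilitySpec, pts: np.ndarray
) -> np.ndarray:
    """(m_responses, n_points) individual desirabilities at coded points."""
    M = model_matrix(pts)
    return np.array(
        [
            individual_desirability(M @ fits[name].beta, spec[name])
            for name in fits
        ]
    )


def _overall(fits, spec, pts: np.ndarray) -> np.ndarray:
    d = _d_matrix(fits, spec, pts)
    m = d.shape[0]
    with np.errstate(divide="ignore"):
        return np.where(
            (d == 0).any(axis=0), 0.0, np.exp(np.log(np.maximum(d, 1e-300)).mean(axis=0))
        )


def optimize_desirability(
    fits: dict[str, QuadraticFit],
    spec: DesirabilitySpec,
    design: DesignMatrix | None = None,
    region: tuple[np.ndarray, np.ndarray] | None = None,
    step: float = 0.02,
    polish_tol: float = 1e-4,
    profile_points: int = 101,
) -> OptimizationResult:
    """Locate the coded factor setting maximizing overall desirability.

    Parameters
    ----------
    fits : {response_name: QuadraticFit}
        One fitted quadratic per response; all must share the same factors.
    spec : DesirabilitySpec
        Goal and anchors per response; keys must match ``fits``.
    design : DesignMatrix, optional
        Supplies the default search region (the per-factor coded range the
        runs actually span) and the real-unit decoding of the optimum.
    region : (low, high) arrays, optional
        Explicit coded search box, overriding the design-derived default.
    step : float
        Coded grid spacing of the exhaustive search stage.
    polish_tol : float
        The coordinate polish halves its step until below this tolerance.
    profile_points : int
        Nodes per factor in the 1-D desirability profile traces.

    Returns
    -------
    OptimizationResult
        Optimum in coded and real units, per-response predictions and
        desirabilities, overall D, and per-factor D-profiles through the
        optimum.  Ties between equal-D grid nodes resolve to the smallest
        coded coordinates in factor order (the cheapest setting when
        factors are ordered temperature, solvent strength, solvent volume).
    """
    if set(fits) != set(spec):
        raise InvalidSpecError(
            f"responses in fits {sorted(fits)} and spec {sorted(spec)} differ"
        )
    if not fits:
        raise InvalidSpecError("no responses to optimize")
    first = next(iter(fits.values()))
    for f in fits.values():
        if f.factor_names != first.factor_names:
            raise InvalidSpecError("all fits must share the same factors")
    k = first.k
    if step <= 0:
        raise InvalidSpecError("grid step must be > 0")

    if region is not None:
        lo = np.asarray(region[0], dtype=float)
        hi = np.asarray(region[1], dtype=float)
    elif design is not None:
        lo, hi = design.coded_bounds()
    else:
        a = (2.0**k) ** 0.25
        lo, hi = np.full(k, -a), np.full(k, a)
    if lo.shape != (k,) or hi.shape != (k,) or np.any(hi <= lo):
        raise InvalidSpecError("search region must satisfy high > low per factor")

    # exhaustive grid stage (np.argmax → first max → lexicographically
    # smallest coordinates, giving the documented tie-break)
    axes = []
    for j in range(k):
        ax = np.arange(lo[j], hi[j] + step * 1e-9, step)
        if ax[-1] < hi[j] - 1e-12:
            ax = np.append(ax, hi[j])
        axes.append(ax)
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(k, -1).T
    D_grid = _overall(fits, spec, grid)
    best = grid[int(np.argmax(D_grid))].copy()

    # shrinking-step coordinate polish
    h = step
    best_D = float(_overall(fits, spec, best[None])[0])
    while h > polish_tol:
        moved = False
        for j in range(k):
            for sgn in (-1.0, 1.0):
                cand = best.copy()
                cand[j] = np.clip(cand[j] + sgn * h, lo[j], hi[j])
                cand_D = float(_overall(fits, spec, cand[None])[0])
                if cand_D > best_D:
                    best, best_D = cand, cand_D
                    moved = True
        if not moved:
            h /= 2.0

    preds = {
        name: float((model_matrix(best[None], k=k) @ f.beta)[0])
        for name, f in fits.items()
    }
    d_vals = {
        name: float(individual_desirability(preds[name], spec[name]))
        for name in fits
    }
    D_opt = overall_desirability(list(d_vals.values()))

    # 1-D profiles of D through the optimum (numeric desirability profiler)
    rows = []
    for j, name in enumerate(first.factor_names):
        levels = np.linspace(lo[j], hi[j], profile_points)
        pts = np.tile(best, (profile_points, 1))
        pts[:, j] = levels
        Dj = _overall(fits, spec, pts)
        for lev, val in zip(levels, Dj):
            rows.append({"factor": name, "coded": lev, "D": val})
    profiles = pd.DataFrame(rows)

    if design is not None:
        real = np.array(
            [f.to_real(c) for f, c in zip(design.factors, best)], dtype=float
        )
        profiles["real"] = [
            design.factors[first.factor_names.index(r.factor)].to_real(r.coded)
            for r in profiles.itertuples()
        ]
    else:
        real = best.copy()

    return OptimizationResult(
        coded_optimum=best,
        real_optimum=real,
        factor_names=list(first.factor_names),
        predicted=preds,
        d=d_vals,
        D=D_opt,
        profiles=profiles,
        region=(lo, hi),
    )
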