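"""Bioassay data reduction: calibration lines, enzyme-inhibition
percentages and IC50, and MIC/MBC calls from broth microdilution series.

Calibration follows classical lab practice: absorbance is regressed on
standard concentration, and unknowns are read off by inverting the line
(and multiplying by any dilution factor).  Enzyme inhibition uses the
two-control formula

    inhibition % = [1 - (A_sample - A_control1) / A_control2] * 100,

where control 1 is the reaction without enzyme (sample background) and
control 2 is enzyme plus substrate without inhibitor (full activity).
IC50 is found either by linear interpolation between the doses bracketing
50% or by a two-parameter log-logistic fit.  MIC is the lowest tested
concentration with no visible growth; MBC/MFC the lowest whose subculture
shows no growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationCurve",
    "DoseResponse",
    "MicrodilutionPlate",
    "MicResult",
    "InvalidStandardsError",
    "NotEstimableError",
    "fit_calibration",
    "apply_calibration",
    "inhibition_percentage",
    "estimate_ic50",
    "determine_mic",
    "determine_mbc",
]


class InvalidStandardsError(ValueError):
    """Calibration standards unusable (too few, or no concentration spread)."""


class NotEstimableError(ValueError):
    """The requested summary cannot be computed from the data given."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line absorbance = slope * concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    r_squared: float


@dataclass(frozen=True)
class DoseResponse:
    """Aligned dose (concentration) and inhibition-percentage vectors."""

    doses: tuple[float, ...]
    inhibition: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        i = np.asarray(self.inhibition, dtype=float)
        if d.size != i.size or d.size == 0:
            raise ValueError("doses and inhibition must align and be nonempty")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be positive and strictly increasing")
        if np.any(i < -10) or np.any(i > 110):
            raise ValueError("inhibition outside the plausible [-10, 110] band")


@dataclass(frozen=True)
class MicrodilutionPlate:
    """Growth/no-growth readings over an increasing dilution series."""

    concentrations: tuple[float, ...]
    visible_growth: tuple[bool, ...]
    subculture_growth: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.visible_growth) != c.size:
            raise ValueError("visible_growth length mismatch")
        if self.subculture_growth is not None and len(self.subculture_growth) != c.size:
            raise ValueError("subculture_growth length mismatch")


@dataclass(frozen=True)
class MicResult:
    """Outcome of a MIC/MBC determination.

    detected is False when growth persisted at every tested concentration
    (the 'ND' outcome).  left_censored marks the boundary case where even
    the lowest tested concentration suppressed growth, so the true value
    may be lower than reported.
    """

    value: float | None
    detected: bool
    left_censored: bool = False


def fit_calibration(
    standards, analyte: str = "standard"
) -> CalibrationCurve:
    """Fit a straight calibration line to (concentration, absorbance) pairs.

    Requires at least 3 standards spanning a nonzero concentration range.
    """
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InvalidStandardsError("need >= 3 (concentration, absorbance) pairs")
    conc, absb = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise InvalidStandardsError("standards have zero concentration spread")
    res = stats.linregress(conc, absb)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(conc.min()), float(conc.max())),
        r_squared=float(res.rvalue**2),
    )


def apply_calibration(
    curve: CalibrationCurve, absorbance: float, dilution_factor: float = 1.0
) -> float:
    """Invert the calibration line and scale by the dilution factor.

    Warns when the back-calculated concentration falls outside the range
    the standards covered.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration line has zero slope")
    conc = (absorbance - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if not lo <= conc <= hi:
        warnings.warn(
            f"back-calculated concentration {conc:.4g} outside the calibrated "
            f"range [{lo:.4g}, {hi:.4g}] for {curve.analyte}",
            RuntimeWarning,
            stacklevel=2,
        )
    return conc * dilution_factor


def inhibition_percentage(
    abs_sample: float, abs_control1: float, abs_control2: float
) -> float:
    """Two-control enzyme-inhibition percentage.

    Not clipped: pathological absorbances can push the value outside
    [0, 100], which is reported as-is with a warning so the raw reduction
    stays faithful to the measurement.
    """
    if abs_control2 == 0:
        raise ZeroDivisionError("abs_control2 (uninhibited activity) is zero")
    pct = (1.0 - (abs_sample - abs_control1) / abs_control2) * 100.0
    if not 0.0 <= pct <= 100.0:
        warnings.warn(
            f"inhibition {pct:.1f}% outside [0, 100]; check controls",
            RuntimeWarning,
            stacklevel=2,
        )
    return pct


def _loglogistic(dose, ic50, hill):
    return 100.0 / (1.0 + (ic50 / dose) ** hill)


def estimate_ic50(dr: DoseResponse, method: str = "interpolation") -> float:
    """Concentration producing 50% inhibition.

    method='interpolation' (default): straight line in concentration
    between the two adjacent doses bracketing 50%, taking the first
    upward crossing.  Suits small dose sets read off a plate.

    method='log_logistic': least-squares fit of
    ``inhibition = 100 / (1 + (IC50/dose)^h)`` (needs >= 4 doses); suits
    richer dose series and tolerates noise.

    Raises NotEstimableError when the data never cross 50%, reporting the
    achievable inhibition range.
    """
    doses = np.asarray(dr.doses, dtype=float)
    inh = np.asarray(dr.inhibition, dtype=float)
    below = inh < 50.0
    if below.all() or (~below).all():
        raise NotEstimableError(
            "inhibition never crosses 50% "
            f"(observed range {inh.min():.1f}%–{inh.max():.1f}%)"
        )
    if method == "interpolation":
        for i in range(len(doses) - 1):
            lo, hi = inh[i], inh[i + 1]
            if lo < 50.0 <= hi:
                frac = (50.0 - lo) / (hi - lo)
                return float(doses[i] + frac * (doses[i + 1] - doses[i]))
        raise NotEstimableError(
            "no adjacent dose pair brackets 50% on the way up"
        )
    if method == "log_logistic":
        if len(doses) < 4:
            raise NotEstimableError("log-logistic fit needs >= 4 doses")
        # initial IC50 from the interpolation estimate when available
        try:
            ic0 = estimate_ic50(dr, method="interpolation")
        except NotEstimableError:
            ic0 = float(np.exp(np.mean(np.log(doses))))
        popt, _ = optimize.curve_fit(
            _loglogistic,
            doses,
            inh,
            p0=(ic0, 1.0),
            bounds=((1e-12, 1e-3), (np.inf, 100.0)),
            maxfev=10000,
        )
        return float(popt[0])
    raise ValueError(f"unknown method {method!r}")


def determine_mic(plate: MicrodilutionPlate) -> MicResult:
    """Lowest tested concentration with no visible growth.

    All-growth plates return the not-detected sentinel; a plate with no
    growth anywhere reports the lowest tested concentration flagged as
    left-censored (the true MIC may be lower).
    """
    growth = np.asarray(plate.visible_growth, dtype=bool)
    if growth.all():
        return MicResult(value=None, detected=False)
    idx = int(np.argmin(growth))  # first False
    return MicResult(
        value=float(plate.concentrations[idx]),
        detected=True,
        left_censored=idx == 0,
    )


def determine_mbc(plate: MicrodilutionPlate) -> MicResult:
    """Lowest concentration whose subculture shows no growth (MBC/MFC)."""
    if plate.subculture_growth is None:
        raise NotEstimableError("no subculture readings; MBC/MFC unavailable")
    growth = np.asarray(plate.subculture_growth, dtype=bool)
    if growth.all():
        return MicResult(value=None, detected=False)
    idx = int(np.argmin(growth))
    return MicResult(
        value=float(plate.concentrations[idx]),
        detected=True,
        left_censored=idx == 0,
    )
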