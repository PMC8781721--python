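"""Validation summaries: fold-ranges across a design and observed-vs-
predicted agreement at the optimum.

The agreement statistic is the coefficient of variation of the
(observed, predicted) pair: 100 * sd / mean, where the sd of a pair is
|difference| / sqrt(2).  A small CV (the usual informal bar is < 7%) says
the verification run landed close to the model's prediction relative to
the magnitude of the response.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["fold_range", "prediction_cv", "validate_predictions"]


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def fold_range(values, sig_figs: int | None = 2) -> float:
    """max/min ratio of a list of positive measurements.

    Reported at 2 significant figures by default (``sig_figs=None`` for the
    raw ratio).  Scale-invariant: multiplying all values by a positive
    constant leaves it unchanged.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("fold_range of an empty list")
    if np.any(vals <= 0):
        raise ValueError("fold_range requires strictly positive values")
    ratio = float(vals.max() / vals.min())
    if sig_figs is None:
        return ratio
    return _round_sig(ratio, sig_figs)


def prediction_cv(observed: float, predicted: float) -> float:
    """Coefficient of variation (%) of an (observed, predicted) pair.

    Symmetric in its arguments; 0 iff the two agree exactly.
    """
    if observed <= 0 or predicted <= 0:
        raise ValueError("prediction_cv requires positive values")
    sd = abs(observed - predicted) / math.sqrt(2.0)
    mean = (observed + predicted) / 2.0
    return 100.0 * sd / mean


def validate_predictions(
    observed: dict[str, float], predicted: dict[str, float], cv_limit: float = 7.0
) -> pd.DataFrame:
    """Per-response observed/predicted comparison table.

    Returns a DataFrame indexed by response with columns observed,
    predicted, cv_percent and within_limit (cv_percent < ``cv_limit``).
    Responses present in only one of the inputs raise a KeyError.
    """
    if set(observed) != set(predicted):
        raise KeyError(
            f"response mismatch: observed {sorted(observed)} vs "
            f"predicted {sorted(predicted)}"
        )
    rows = {}
    for name in observed:
        cv = prediction_cv(observed[name], predicted[name])
        rows[name] = {
            "observed": observed[name],
            "predicted": predicted[name],
            "cv_percent": cv,
            "within_limit": cv < cv_limit,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
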