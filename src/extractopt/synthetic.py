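"""Seeded generators of synthetic study inputs.

Every stage of the analysis can be exercised without laboratory data:

* a CCD response table drawn from a known quadratic surface plus i.i.d.
  homoscedastic Gaussian noise (the minimal error model consistent with
  replicated center points);
* a monotone log-logistic dose-response series with known IC50 and Hill
  slope;
* a growth/no-growth microdilution series with known MIC.

All generators are pure functions of their arguments including the seed,
so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioassay import DoseResponse, MicrodilutionPlate
from .design import DesignMatrix, FactorDef, generate_rotatable_ccd
from .rsm import model_matrix, quadratic_terms

__all__ = [
    "SyntheticCcdSpec",
    "n_quadratic_terms",
    "simulate_ccd_experiment",
    "simulate_dose_response",
    "simulate_microdilution",
]


def n_quadratic_terms(k: int) -> int:
    """Terms in the full second-order model: 1 + 2k + k(k-1)/2."""
    return 1 + 2 * k + k * (k - 1) // 2


@dataclass
class SyntheticCcdSpec:
    """Ground truth for a simulated CCD experiment.

    true_beta maps each response name to its coefficient vector on the
    coded scale, in canonical term order (intercept, linear, quadratic,
    interactions); sigma gives the per-response noise standard deviation
    in response units (a scalar applies to all responses).
    """

    factors: list[FactorDef]
    n_center: int
    true_beta: Mapping[str, Sequence[float]]
    sigma: Mapping[str, float] | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = n_quadratic_terms(len(self.factors))
        for name, beta in self.true_beta.items():
            if len(beta) != p:
                raise ValueError(
                    f"response {name!r}: expected {p} coefficients, "
                    f"got {len(beta)}"
                )
        sigmas = self.sigma_map().values()
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sd must be >= 0")

    def sigma_map(self) -> dict[str, float]:
        if isinstance(self.sigma, Mapping):
            return {k: float(v) for k, v in self.sigma.items()}
        return {name: float(self.sigma) for name in self.true_beta}


def simulate_ccd_experiment(
    spec: SyntheticCcdSpec,
) -> tuple[DesignMatrix, pd.DataFrame]:
    """Draw one CCD experiment from the spec's quadratic surfaces.

    Returns the rotatable design and a response table indexed by run_id
    with one column per response, generated as
    ``quadratic(true_beta, coded point) + N(0, sigma^2)`` i.i.d. per run.
    """
    design = generate_rotatable_ccd(spec.factors, spec.n_center)
    X = model_matrix(design.coded)
    rng = np.random.default_rng(spec.seed)
    sig = spec.sigma_map()
    data = {}
    for name, beta in spec.true_beta.items():
        mean = X @ np.asarray(beta, dtype=float)
        noise = rng.normal(0.0, sig[name], size=design.n_runs) if sig[name] > 0 else 0.0
        data[name] = mean + noise
    responses = pd.DataFrame(data, index=pd.Index(design.run_ids, name="run_id"))
    return design, responses


def simulate_dose_response(
    ic50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Log-logistic inhibition curve with additive Gaussian noise.

    ``inhibition = 100 / (1 + (ic50/dose)^hill) + N(0, noise_sd^2)``,
    clipped into the plausible [-10, 110] band the DoseResponse container
    accepts.
    """
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be > 0")
    d = np.asarray(doses, dtype=float)
    inh = 100.0 / (1.0 + (ic50 / d) ** hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inh = inh + rng.normal(0.0, noise_sd, size=d.size)
    inh = np.clip(inh, -10.0, 110.0)
    return DoseResponse(doses=tuple(d), inhibition=tuple(inh))


def simulate_microdilution(
    true_mic: float,
    concentrations: Sequence[float],
    true_mbc: float | None = None,
) -> MicrodilutionPlate:
    """Deterministic plate: growth persists strictly below the true MIC.

    Subculture growth follows the true MBC when given (>= true MIC),
    otherwise mirrors the visible-growth pattern.
    """
    c = np.asarray(concentrations, dtype=float)
    visible = tuple(bool(x < true_mic) for x in c)
    threshold = true_mic if true_mbc is None else true_mbc
    sub = tuple(bool(x < threshold) for x in c)
    return MicrodilutionPlate(
        concentrations=tuple(c), visible_growth=visible, subculture_growth=sub
    )
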