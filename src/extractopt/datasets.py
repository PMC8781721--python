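"""Packaged umbu-peel extraction study data.

The package ships the complete 17-run rotatable CCD used to optimize
thermal-assisted solid-liquid extraction of bioactive compounds from umbu
(*Spondias tuberosa*) fruit peel: three factors (extraction temperature,
ethanol concentration of the solvent, solid-liquid ratio) and five measured
responses (total phenolics TPC, total flavonoids TFC, and antioxidant
capacity by ABTS, DPPH and FRAP), plus the verification values measured at
the optimized condition and a static table of metabolites annotated in the
optimized extract by LC-HRMS.

Factor axes: temperature center 52.5 °C, half-range 12.5 °C; ethanol center
55%, half-range 25%; solid-liquid ratio (the n of 1:n, mL solvent per g
solid) center 35, half-range 15.  The tabulated run levels are the values
actually reported for the experiment (axial levels rounded to instrument
precision, e.g. 74 °C rather than the exact 73.52 of coded +1.68179), and
coded levels are always derived from these real levels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import DesignMatrix, FactorDef

__all__ = [
    "RESPONSE_UNITS",
    "umbu_factors",
    "load_umbu_design",
    "load_umbu_responses",
    "load_umbu_observed_optimum",
    "load_umbu_metabolites",
]

#: Measurement units of the five response channels.
RESPONSE_UNITS = {
    "TPC": "mg GAE/100 g",
    "TFC": "mg RE/100 g",
    "ABTS": "µmol TE/g",
    "DPPH": "µmol TE/g",
    "FRAP": "µmol Fe2+/g",
}


def _data_path(name: str):
    return resources.files("extractopt.data").joinpath(name)


def umbu_factors() -> list[FactorDef]:
    """The three extraction factors with their real-to-coded axes."""
    return [
        FactorDef("temperature", "°C", center=52.5, half_range=12.5),
        FactorDef("ethanol", "%", center=55.0, half_range=25.0),
        FactorDef("solid_liquid", "mL solvent per g solid", center=35.0, half_range=15.0),
    ]


def load_umbu_design() -> DesignMatrix:
    """The 17-run design (8 factorial + 6 axial + 3 center replicates)."""
    factors = umbu_factors()
    with resources.as_file(_data_path("umbu_peel_design.csv")) as path:
        return DesignMatrix.read_csv(path, factors)


def load_umbu_responses() -> pd.DataFrame:
    """Measured responses per run, indexed by run_id (columns TPC..FRAP)."""
    with resources.as_file(_data_path("umbu_peel_responses.csv")) as path:
        return pd.read_csv(path, index_col="run_id")


def load_umbu_observed_optimum() -> dict[str, float]:
    """Verification measurements at the optimized extraction condition."""
    with resources.as_file(_data_path("umbu_peel_observed_optimum.csv")) as path:
        df = pd.read_csv(path)
    return dict(zip(df["response"], df["observed"].astype(float)))


def load_umbu_metabolites() -> pd.DataFrame:
    """Static LC-HRMS annotation table of the optimized extract.

    Carried as metadata only; no mass-spectrometry processing is done here.
    """
    with resources.as_file(_data_path("umbu_peel_metabolites.csv")) as path:
        return pd.read_csv(path)
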