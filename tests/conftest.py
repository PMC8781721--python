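import numpy as np
import pytest

import extractopt as xo


@pytest.fixture(scope="session")
def umbu_design():
    return xo.datasets.load_umbu_design()


@pytest.fixture(scope="session")
def umbu_responses():
    return xo.datasets.load_umbu_responses()


@pytest.fixture(scope="session")
def umbu_fits(umbu_design, umbu_responses):
    return {
        name: xo.fit_quadratic(umbu_design, umbu_responses[name], name)
        for name in umbu_responses.columns
    }


@pytest.fixture(scope="session")
def umbu_report(umbu_design, umbu_responses):
    """Full pipeline run on the packaged umbu peel study, shared per session."""
    return xo.run_full_analysis(
        umbu_design,
        umbu_responses,
        observed_optimum=xo.datasets.load_umbu_observed_optimum(),
    )


@pytest.fixture(scope="session")
def three_factors():
    return [
        xo.FactorDef("temperature", "°C", 52.5, 12.5),
        xo.FactorDef("ethanol", "%", 55.0, 25.0),
        xo.FactorDef("solid_liquid", "mL/g", 35.0, 15.0),
    ]


def normal_equations_ols(X: np.ndarray, y: np.ndarray):
    """Independent brute-force OLS oracle: beta = (X'X)^-1 X'y, textbook SEs."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    mse = resid @ resid / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * mse)
    return beta, se, resid
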