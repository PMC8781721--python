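"""Parameter recovery on a simulated CCD experiment.

Draws a response table from a known quadratic surface plus Gaussian noise,
refits the model, and compares estimated coefficients (with 95% confidence
intervals) against the truth — the basic calibration check for the whole
fitting chain.
"""

import numpy as np
from scipy import stats

import extractopt as xo

factors = [
    xo.FactorDef("temperature", "°C", 52.5, 12.5),
    xo.FactorDef("ethanol", "%", 55.0, 25.0),
    xo.FactorDef("solid_liquid", "mL/g", 35.0, 15.0),
]
true_beta = np.array([1420.0, 180.0, -280.0, 90.0, 25.0, -150.0, -40.0,
                      30.0, -20.0, 10.0])

spec = xo.SyntheticCcdSpec(factors, n_center=3, true_beta={"y": true_beta},
                           sigma=50.0, seed=2024)
design, responses = xo.simulate_ccd_experiment(spec)
fit = xo.fit_quadratic(design, responses["y"])

tcrit = stats.t.ppf(0.975, fit.df_residual)
print(f"noise sd 50, R² of refit = {fit.r_squared:.3f}\n")
print("term             true     estimate    95% CI           covered")
for term, bt, bh, se in zip(fit.terms, true_beta, fit.beta, fit.se):
    lo, hi = bh - tcrit * se, bh + tcrit * se
    print(f"{term:14s} {bt:8.1f}   {bh:8.1f}   [{lo:8.1f},{hi:8.1f}]   "
          f"{lo <= bt <= hi}")
print(
    "\nWith homoscedastic Gaussian noise, each interval covers its true "
    "coefficient about 95% of the time over repeated simulations."
)
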