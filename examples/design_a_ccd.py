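"""Construct a rotatable central composite design for a 3-factor study.

Shows the canonical run order (factorial corners, axial stars, center
replicates) and the real-unit levels each coded setting maps onto.
"""

import extractopt as xo

factors = [
    xo.FactorDef("temperature", "°C", center=52.5, half_range=12.5),
    xo.FactorDef("ethanol", "%", center=55.0, half_range=25.0),
    xo.FactorDef("solid_liquid", "mL solvent per g solid", center=35.0, half_range=15.0),
]

design = xo.generate_rotatable_ccd(factors, n_center=3)
print(
    f"{design.n_runs} runs for k=3 factors: 8 factorial + 6 axial + 3 center"
)
print(f"axial distance alpha = (2^3)^(1/4) = {design.alpha:.5f}\n")
print(design.to_frame().round(3).to_string(index=False))
print(
    "\nEach axial run perturbs a single factor to ±alpha in coded units;\n"
    "e.g. coded +alpha in temperature is "
    f"{factors[0].to_real(design.alpha):.1f} °C. Replicated center points\n"
    "provide the pure-error estimate the lack-of-fit test needs."
)
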