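"""Call MIC and MBC from a broth-microdilution series.

Builds a plate over the two-fold dilution ladder 0.03-0.24 mg GAE/mL with
a known inhibitory threshold, then applies the visual-growth (MIC) and
subculture (MBC) decision rules.
"""

import extractopt as xo

conc = (0.03, 0.06, 0.12, 0.24)
plate = xo.simulate_microdilution(true_mic=0.06, concentrations=conc,
                                  true_mbc=0.12)

print("concentration  visible growth  subculture growth")
for c, v, s in zip(plate.concentrations, plate.visible_growth,
                   plate.subculture_growth):
    print(f"  {c:9.2f}       {str(v):5s}           {str(s):5s}")

mic = xo.determine_mic(plate)
mbc = xo.determine_mbc(plate)
print(f"\nMIC = {mic.value} mg GAE/mL (lowest well with no visible growth)")
print(f"MBC = {mbc.value} mg GAE/mL (lowest well whose subculture is sterile)")

all_growth = xo.simulate_microdilution(true_mic=1.0, concentrations=conc)
nd = xo.determine_mic(all_growth)
print(
    f"\nA plate with growth everywhere reports detected={nd.detected} "
    "(the 'ND' outcome: the MIC exceeds the highest tested concentration)."
)
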