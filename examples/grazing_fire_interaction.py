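"""How the carbon-optimal grazing intensity shifts with fire frequency.

Sweeps equilibrium SOC over grazing intensity at four fire frequencies for
a dry, fine-textured grassland (450 mm/yr, 25% sand, lignin+cellulose 0.3).
With frequent fire, intermediate grazing maximises soil carbon: grazed
biomass ends up as dung-derived carbon instead of burning.
"""

import numpy as np

import snapsoc as sp

gis = np.linspace(0.0, 0.95, 96)
print(f"{'fire':>5} {'best gi':>8} {'SOC_eq(best)':>13} {'SOC_eq(gi=0)':>13} {'gain':>6}")
for fire in (0.0, 0.25, 0.5, 0.75):
    vals = [
        sp.soc_equilibrium(
            sp.SiteConditions(rain=450.0, gi=g, fire=fire, ligcell=0.3, sand_pct=25.0)
        )
        for g in gis
    ]
    i = int(np.argmax(vals))
    gain = vals[i] / vals[0] - 1
    print(f"{fire:5.2f} {gis[i]:8.2f} {vals[i]:13.0f} {vals[0]:13.0f} {gain:5.1%}")
# The optimum moves from ~0.4 (no fire, ~3% gain) to ~0.65 with fire in
# 3 of 4 years (~20% gain over the ungrazed stock).
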