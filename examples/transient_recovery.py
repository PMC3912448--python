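"""Transient SOC recovery of a degraded (carbon-free) soil.

Iterates the annual mass balance from a zero stock and reports progress
toward the closed-form equilibrium; convergence is geometric because the
annual update is an affine contraction.
"""

import snapsoc as sp

site = sp.SiteConditions(rain=650.0, gi=0.4, fire=0.3, ligcell=0.3, sand_pct=40.0)
eq = sp.soc_equilibrium(site)
traj = sp.simulate_trajectory(site, soc0=0.0, years=100_000)

print(f"equilibrium SOC: {eq:.0f} gC/m2;  converged in {len(traj.years) - 1} years")
for year in (0, 10, 25, 50, 100, 200):
    if year < len(traj.soc):
        print(f"  year {year:4d}: {traj.soc[year]:8.0f} gC/m2 ({traj.soc[year] / eq:5.1%} of equilibrium)")
# Recovery is slow: decades to approach equilibrium, because only a small
# fraction of the stock turns over in any year.
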