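"""Re-fit the grazing response of leaf area index from (synthetic) data.

Generates a noisy sample from the exponential-collapse response
LAI = B0 - B1*exp(B2*GI) and recovers the coefficients by multi-start
nonlinear least squares — the workflow for transferring the model to a
new grassland where the compensation response has been measured.
"""

import snapsoc as sp

gi, lai = sp.generate_lai_dataset(n=36, b0=1.15, b1=0.015, b2=4.6, sigma=0.05, seed=7)
fit = sp.fit_lai_response(gi, lai)

print(f"B0 = {fit.b0:7.3f} +/- {fit.se_b0:.3f}   (true 1.150)")
print(f"B1 = {fit.b1:7.4f} +/- {fit.se_b1:.4f}  (true 0.0150)")
print(f"B2 = {fit.b2:7.2f} +/- {fit.se_b2:.2f}    (true 4.60)")
print(f"R^2 = {fit.r_squared:.2f}, converged={fit.converged}")

# Plug the re-fitted response into the full model:
coeffs = sp.default_coefficients().with_values(
    name="refit-lai", lai_b1=fit.b1, lai_b2=fit.b2
)
site = sp.SiteConditions(rain=650.0, gi=0.6, fire=0.5, ligcell=0.3, sand_pct=40.0)
print(f"SOC_eq with refit coefficients: {sp.soc_equilibrium(site, coeffs):.0f} gC/m2")
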