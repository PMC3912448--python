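# Methods

## Model structure and assumptions

snapsoc implements an annual-timestep mass balance for the *stable* soil
organic carbon (SOC) of a tropical grassland: only the lignin+cellulose
fraction of plant tissue is tracked, on the assumption that all other
fixed carbon is assimilated and respired (by grazers, soil microbes or
macro-decomposer guts) within a year or two and never accumulates. One
wet season per year produces above- and belowground biomass; aboveground
biomass is partitioned among consumption by grazers (fraction GI),
combustion (fraction FIRE of what grazers left), and decomposition into
soil; consumed stable carbon returns as dung, assumed fully incorporated
into soil by termites and dung beetles. Losses are microbial respiration
on days with soil moisture above a 10% gravimetric threshold. There are
no nitrogen, temperature, or multi-pool dynamics: across the calibration
region's rainfall gradient, moisture dominates both production and
microbial activity, and tropical soil temperatures vary too little
(~3 °C/yr) to carry explanatory power.

Grazing enters production through plant compensation: the proportion of
aboveground biomass held as leaf rises linearly with grazing intensity
(P_L = 0.6 + 0.24·GI), and leaf area index follows
LAI = P_L/0.6 − 0.015·exp(4.6·GI), so LAI (and hence realised production
ANPP_est = LAI·ANPP_max) is maintained or slightly elevated up to ~70%
grazing and collapses toward zero above ~95%.

## Parameters

All empirical constants live in a `CoefficientSet` with per-coefficient
standard errors. Two sets ship:

- `text-equations` (default): the constants of the model equations as
  written above; used for all deterministic predictions and validation.
- `table2-mc`: the independently reported regression estimates used as
  Monte Carlo sampling distributions. A few differ slightly from the
  equation constants (leaf-proportion intercept 0.597 vs 0.6; belowground
  production 958.8/−0.82 vs 917.4/−0.763; wet-day slope 0.00043 vs
  0.00044; respiration intercept −0.58 vs −0.579). The two sets are kept
  separate and selectable; they are never merged.

The water-holding-capacity adjustment (1.33 − 0.0075·SAND%) is the
literature WHC regression with two standard deviations added to the
intercept, converting it into a multiplier around 1 (unity at 44% sand);
the raw WHC coefficients (1.04 ± 0.05, −0.0070 ± 0.0008) are carried in
the registry for reference. Fixed constants — season length 240 d, root
lignin+cellulose offset +0.05, tissue carbon fraction 0.45, the
respiration access factor 0.7 + 0.3·SAND%/100 — have zero standard error
except the carbon fraction (±0.02).

Units: all areal quantities are g/m² (carbon as gC/m²); SOC stocks are
integrated to 40 cm depth; rainfall in mm/yr; proportions in [0, 1].

## Numerical choices

- **Clamps.** LAI is clamped at 0 (the raw curve goes negative above
  GI ≈ 0.977); WETDAYS is clamped to [0, 240]; the respiration daily
  maximum rate is clamped at 0 in transient simulation so that stocks
  below ~1316 gC/m² cannot gain carbon from "negative respiration". The
  closed-form equilibrium is evaluated from the unclamped respiration
  line, which is valid because the equilibrium
  SOC_eq = inputs/(0.00044·W·f) + 0.579/0.00044 always lies at or above
  the clamp boundary, where the two forms coincide. Clamp events are
  countable via `ClampLog` and reported by the CLI.
- **Validity envelope.** Production predictions refuse rainfall outside
  (≈32.7, ≈1202.4) mm/yr — the roots of the two production regressions —
  rather than extrapolating to negative production; the equilibrium
  additionally requires WETDAYS > 0 (rain above ≈57 mm/yr). Explicit
  point predictions fail loudly on violations; grid sweeps mark offending
  cells NaN and count them.
- **Trajectories.** The annual map is an affine contraction (slope
  1 − 0.00044·W·f, always in (0, 1)), so iteration converges geometrically
  from any start; the integrator stops when |ΔSOC| < 10⁻⁶·SOC_eq, with a
  user-supplied year cap as a safety net, and clamps stocks at 0 from
  below.
- **LAI fit.** The nonlinear response LAI = B0 − B1·exp(B2·GI) is fitted
  by least squares multi-started over B2 ∈ {1, 3, 5, 8} (exponential-rate
  fits are start-sensitive); coefficient standard errors come from the
  curvature at the optimum. The parameterization uses a positive rate
  inside the exponential with B1, B2 > 0; a prose convention writing
  −B2·GI with negative B1 describes the same curve.
- **Tolerances in tests.** Pure single-equation identities are checked at
  1e-9 relative; chained worked examples at 1e-3; iterated-vs-closed-form
  equilibria at 0.1% across 200 random sites.

## Monte Carlo and sensitivity

Each Monte Carlo draw samples every regression coefficient — and each
site driver with a reported measurement error (grazing intensity and
lignin+cellulose from N=3 plots, rainfall from the 9-year record) —
independently from Normal(estimate, SE). Coefficients are sampled
independently because no covariance matrices were published for the
underlying regressions; this overstates the variance where coefficients
are anti-correlated (intercept/slope pairs) and is a known limitation.
Draws violating a domain invariant (proportions outside their ranges,
rainfall outside the support, zero wet days) are rejected, not clipped,
so the retained sample is not piled onto the boundaries; retained counts
are reported and `retained + rejected = n_draws`.

Summaries report the draw mean, the standard error of that mean
(sem = sd/√n_retained), the draw standard deviation (the propagated
standard error of a single prediction) and cv = sd/mean. The draw
distribution is heavy-tailed at dry sites: low-rainfall draws shrink the
number of wet days, which sits in the equilibrium's denominator, so
single-replicate summaries of the spread are themselves noisy.

The sensitivity analysis perturbs each driver by +10% at three levels
(rain 450/650/900; fire 0.25/0.50/0.75; GI 0.25/0.60/0.90; lignin+
cellulose 0.15/0.25/0.35; sand 25/45/70), against either the full 3⁴
factorial of the other drivers' levels (default; the spread over
backgrounds gives the reported SE) or a medium-only background. Perturbed
proportions escaping [0, 1] are clipped with a warning. The dominant cell
is grazing intensity at its high level (0.90 → 0.99): the +10% change
pushes the system over the LAI collapse, changing equilibrium SOC by ~21%
on average, roughly twice the effect of a 10% rainfall change and an
order of magnitude above the fire and sand cells.

## Synthetic data

`generate_synthetic_sites` draws the five drivers independently and
uniformly over ranges inside the validity envelope (rain 100–1100 mm/yr,
GI and fire 0–1, lignin+cellulose 0.10–0.50, sand 0–100%); it emulates
the *range* of conditions the model accepts, not the empirical joint
distribution of real landscapes (where, e.g., rainfall and soil texture
co-vary), so property tests built on it certify model structure, not
predictive skill on real data. `generate_lai_dataset` draws GI uniformly
on [0, 1) and adds Gaussian noise (default σ = 0.05, n = 36, matching the
scale of the original compensation experiment) to the exponential LAI
response; recovery tests (200 replicates) require median coefficient
biases within twice the reported standard errors (0.027, 0.0011, 0.2).

## Validation and its caveat

The packaged fixture transcribes the grazed-plot site means of the
eight-site, 9-year Serengeti exclosure experiment (drivers, soil %C,
bulk density, texture; fire frequency = fires observed in 2000–2008
divided by 9). Observed stocks are reconstructed as
soil C%/100 × bulk density × 40 cm × 10⁴ gC/m², and
`validate_site_level` regresses observed on predicted (OLS), reporting
R², slope ± SE, intercept ± SE and z-tests of slope = 1 / intercept = 0.
A plot-level code path accepts user-supplied per-plot tables; per-plot
drivers for the original experiment were never published.

**Validation caveat.** With these printed site-mean inputs the model
over-predicts the two dry shortgrass sites (both the belowground-
production and wet-day regressions push dry sites toward high equilibria)
and under-predicts the mesic savanna sites; the resulting regression is
flat (R² ≈ 0.003, slope ≈ −0.03, intercept ≈ 9139 gC/m²), far from the
originally published strong site-level fit. The discrepancy is not a
coefficient-choice issue — no combination of the shipped coefficient
variants or plausible structural readings of the input terms recovers a
strong fit — and the reconstruction of observed stocks from the printed
%C and bulk density exceeds the observed range quoted alongside the
original analysis, indicating that the published fit rests on per-site or
per-plot data that were not printed. The package reports what the printed
inputs actually give.

## Known limitations

- Mean-annual forcing only: no within-year dynamics, no stochastic
  weather sequences (scenario sweeps substitute).
- Single stable-carbon pool; no nitrogen or temperature response.
- Independence assumptions in the Monte Carlo (see above).
- The fire–grazing interaction at *zero* fire is not strictly monotone in
  grazing: dung inputs plus compensation give a shallow (~3%) interior
  maximum near GI ≈ 0.4 before the collapse at high grazing; statements
  that the ungrazed stock is maximal at zero fire hold only approximately.
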