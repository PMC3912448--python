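"""Annual carbon-flux equations of the SNAP model.

The model describes a grazed tropical grassland with an annual time step
and five drivers: mean annual rainfall (mm/yr), grazing intensity
(GI = 1 - grazed/ungrazed standing biomass), fire frequency (expected
fraction of years that burn), the lignin+cellulose fraction of aboveground
biomass, and soil sand content (%).  Only the recalcitrant
(lignin+cellulose) carbon is tracked: everything else is assumed to be
respired by herbivores, microbes or macro-decomposers within a year or two.

Fluxes (all g m^-2 yr^-1; carbon fluxes as gC m^-2 yr^-1):

* potential aboveground production from rainfall, scaled by a soil-texture
  water-holding-capacity adjustment;
* realised aboveground production = potential production x LAI, where leaf
  area index responds to grazing through compensatory reallocation from
  stem to leaf (LAI is roughly flat up to ~70% grazing, then collapses);
* belowground production declining linearly with rainfall;
* plant-derived stable-carbon input: shoots that are neither eaten nor
  burned, plus roots (5 percentage points richer in lignin+cellulose);
* dung-derived stable-carbon input: the recalcitrant fraction of what
  grazers consume, assumed fully incorporated into soil by dung beetles
  and termites;
* microbial respiration: a linear maximum daily rate in the SOC stock,
  active only on days the soil is above 10% gravimetric moisture, with
  easier substrate access in sandier soils.

All operations are pure functions of their inputs and a
:class:`~snapsoc.coefficients.CoefficientSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .coefficients import CoefficientSet, DomainError, default_coefficients

__all__ = [
    "SiteConditions",
    "FluxBreakdown",
    "ClampLog",
    "proportion_leaf",
    "leaf_area_index",
    "adjusted_whc",
    "anpp_max",
    "anpp_est",
    "bnpp_est",
    "plant_derived_soc",
    "dung_derived_soc",
    "wetdays",
    "microbial_respiration",
    "evaluate_fluxes",
    "rain_support",
]


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise DomainError(message)


@dataclass(frozen=True)
class SiteConditions:
    """The five environmental drivers for one site or scenario.

    Optional ``se_*`` fields carry measurement standard errors of the
    drivers estimated in the field (grazing intensity and lignin+cellulose
    from replicate plots, rainfall from inter-annual variation); they are
    used only by the Monte Carlo machinery.
    """

    rain: float  # mean annual rainfall, mm/yr
    gi: float  # grazing intensity, proportion in [0, 1]
    fire: float  # fire frequency, fraction of years burning, [0, 1]
    ligcell: float  # lignin+cellulose fraction of aboveground biomass, (0, 1)
    sand_pct: float  # soil sand content, percent [0, 100]
    name: str | None = None
    se_gi: float = 0.0
    se_ligcell: float = 0.0
    se_rain: float = 0.0

    def __post_init__(self) -> None:
        _check(self.rain > 0, f"rain must be > 0 mm/yr, got {self.rain}")
        _check(0 <= self.gi <= 1, f"gi must be in [0, 1], got {self.gi}")
        _check(0 <= self.fire <= 1, f"fire must be in [0, 1], got {self.fire}")
        _check(0 < self.ligcell < 1, f"ligcell must be in (0, 1), got {self.ligcell}")
        _check(
            0 <= self.sand_pct <= 100,
            f"sand_pct must be in [0, 100], got {self.sand_pct}",
        )
        for fld in ("se_gi", "se_ligcell", "se_rain"):
            _check(getattr(self, fld) >= 0, f"{fld} must be >= 0")


@dataclass(frozen=True)
class FluxBreakdown:
    """One annual evaluation of every intermediate model quantity."""

    p_leaf: float  # proportion of aboveground biomass as leaf
    lai: float  # leaf area index, dimensionless
    anpp_max: float  # potential aboveground production, g/m2/yr
    anpp_est: float  # grazer-modified aboveground production, g/m2/yr
    bnpp_est: float  # belowground production, g/m2/yr
    pdsoc: float  # plant-derived stable C input, gC/m2/yr
    ddsoc: float  # dung-derived stable C input, gC/m2/yr
    wetdays: float  # microbially active days, d/yr
    mresp: float  # microbial respiration at the given SOC state, gC/m2/yr
    delta_soc: float  # net annual SOC change, gC/m2/yr


@dataclass
class ClampLog:
    """Counts of physical-range clamps applied during evaluations."""

    lai: int = 0
    wetdays: int = 0
    respiration: int = 0

    def total(self) -> int:
        return self.lai + self.wetdays + self.respiration


def rain_support(coeffs: CoefficientSet | None = None) -> tuple[float, float]:
    """Open rainfall interval (mm/yr) on which both production regressions
    return positive values; predictions outside it are refused rather than
    extrapolated."""
    c = coeffs or default_coefficients()
    lo = -c.anpp_intercept / c.anpp_slope  # ~32.7 with defaults
    hi = -c.bnpp_intercept / c.bnpp_slope  # ~1202 with defaults
    return lo, hi


def proportion_leaf(gi: float, coeffs: CoefficientSet | None = None) -> float:
    """Proportion of aboveground biomass allocated to leaf at grazing
    intensity ``gi`` (rises with grazing as plants trade stem for leaf)."""
    c = coeffs or default_coefficients()
    _check(0 <= gi <= 1, f"gi must be in [0, 1], got {gi}")
    return c.pl_intercept + c.pl_slope * gi


def leaf_area_index(
    gi: float,
    coeffs: CoefficientSet | None = None,
    log: ClampLog | None = None,
) -> float:
    """Leaf area index under grazing: a leaf-proportion boost divided by the
    ungrazed leaf share, minus an exponential collapse term.

    Negative raw values (possible only at the most extreme grazing) are
    clamped to zero: leaf area is a physical quantity.
    """
    c = coeffs or default_coefficients()
    raw = proportion_leaf(gi, c) / c.pl_intercept - c.lai_b1 * math.exp(c.lai_b2 * gi)
    if raw < 0:
        if log is not None:
            log.lai += 1
        return 0.0
    return raw


def adjusted_whc(sand_pct: float, coeffs: CoefficientSet | None = None) -> float:
    """Water-holding-capacity adjustment of potential production for soil
    texture (unity near 44% sand with default coefficients)."""
    c = coeffs or default_coefficients()
    _check(0 <= sand_pct <= 100, f"sand_pct must be in [0, 100], got {sand_pct}")
    return c.awhc_intercept + c.awhc_slope * sand_pct


def anpp_max(
    rain: float, sand_pct: float, coeffs: CoefficientSet | None = None
) -> float:
    """Potential (ungrazed) aboveground production, g/m2/yr."""
    c = coeffs or default_coefficients()
    lo, _ = rain_support(c)
    _check(rain > lo, f"rainfall below model support ({rain} <= {lo:.1f} mm/yr)")
    return (c.anpp_slope * rain + c.anpp_intercept) * adjusted_whc(sand_pct, c)


def anpp_est(
    rain: float,
    sand_pct: float,
    gi: float,
    coeffs: CoefficientSet | None = None,
    log: ClampLog | None = None,
) -> float:
    """Grazer-modified aboveground production: potential production times
    the grazing response of leaf area index.  Can exceed the potential at
    low to intermediate grazing (compensation) and approaches zero as
    grazing intensity approaches 1."""
    c = coeffs or default_coefficients()
    return anpp_max(rain, sand_pct, c) * leaf_area_index(gi, c, log)


def bnpp_est(rain: float, coeffs: CoefficientSet | None = None) -> float:
    """Belowground production, declining linearly with rainfall, g/m2/yr."""
    c = coeffs or default_coefficients()
    _, hi = rain_support(c)
    _check(
        rain < hi,
        f"rainfall outside belowground-production support ({rain} >= {hi:.1f} mm/yr)",
    )
    return c.bnpp_intercept + c.bnpp_slope * rain


def plant_derived_soc(
    anpp_est: float,
    bnpp_est: float,
    gi: float,
    fire: float,
    ligcell: float,
    coeffs: CoefficientSet | None = None,
) -> float:
    """Annual plant-derived stable-carbon input to soil, gC/m2/yr.

    Shoot litter contributes only the fraction neither grazed (1-GI) nor
    burned (1-FIRE); roots contribute in full, with a lignin+cellulose
    fraction 5 percentage points above that of shoots.
    """
    c = coeffs or default_coefficients()
    _check(0 <= gi <= 1, f"gi must be in [0, 1], got {gi}")
    _check(0 <= fire <= 1, f"fire must be in [0, 1], got {fire}")
    _check(0 <= ligcell < 1, f"ligcell must be in [0, 1), got {ligcell}")
    root_lc = ligcell + c.root_ligcell_offset
    _check(
        root_lc < 1,
        f"ligcell + root offset must be < 1, got {root_lc}",
    )
    return c.carbon_frac * (
        ligcell * anpp_est * (1 - gi) * (1 - fire) + root_lc * bnpp_est
    )


def dung_derived_soc(
    anpp_est: float,
    gi: float,
    ligcell: float,
    coeffs: CoefficientSet | None = None,
) -> float:
    """Annual dung-derived stable-carbon input to soil, gC/m2/yr: the
    recalcitrant fraction of consumed production, all incorporated into
    soil by macro-decomposers."""
    c = coeffs or default_coefficients()
    _check(0 <= gi <= 1, f"gi must be in [0, 1], got {gi}")
    _check(0 <= ligcell < 1, f"ligcell must be in [0, 1), got {ligcell}")
    return ligcell * c.carbon_frac * gi * anpp_est


def wetdays(
    rain: float,
    coeffs: CoefficientSet | None = None,
    log: ClampLog | None = None,
) -> float:
    """Days per year with soil moisture above the microbial-activity
    threshold, clamped to [0, season length]."""
    c = coeffs or default_coefficients()
    _check(rain > 0, f"rain must be > 0 mm/yr, got {rain}")
    raw = (c.wet_slope * rain + c.wet_intercept) * c.season_days
    if raw < 0:
        if log is not None:
            log.wetdays += 1
        return 0.0
    return min(raw, c.season_days)


def microbial_respiration(
    soc: float,
    sand_pct: float,
    wetdays: float,
    coeffs: CoefficientSet | None = None,
    log: ClampLog | None = None,
    clamp: bool = True,
) -> float:
    """Annual microbial respiration loss at SOC stock ``soc`` (gC/m2 to
    40 cm), gC/m2/yr.

    The maximum daily rate is linear in SOC and goes negative below a small
    stock (~1316 gC/m2 with defaults); with ``clamp=True`` (the default for
    transient simulation) the rate is floored at zero so respiration cannot
    create carbon.
    """
    c = coeffs or default_coefficients()
    _check(soc >= 0, f"soc must be >= 0, got {soc}")
    _check(0 <= sand_pct <= 100, f"sand_pct must be in [0, 100], got {sand_pct}")
    _check(wetdays >= 0, f"wetdays must be >= 0, got {wetdays}")
    daily_max = c.mresp_slope * soc + c.mresp_intercept
    if clamp and daily_max < 0:
        if log is not None:
            log.respiration += 1
        daily_max = 0.0
    access = c.sand_access_base + c.sand_access_span * sand_pct / 100.0
    return wetdays * access * daily_max


def evaluate_fluxes(
    site: SiteConditions,
    soc: float,
    coeffs: CoefficientSet | None = None,
    log: ClampLog | None = None,
) -> FluxBreakdown:
    """Evaluate every model quantity for one year at SOC state ``soc``."""
    c = coeffs or default_coefficients()
    pl = proportion_leaf(site.gi, c)
    lai = leaf_area_index(site.gi, c, log)
    amax = anpp_max(site.rain, site.sand_pct, c)
    aest = amax * lai
    best = bnpp_est(site.rain, c)
    pd = plant_derived_soc(aest, best, site.gi, site.fire, site.ligcell, c)
    dd = dung_derived_soc(aest, site.gi, site.ligcell, c)
    wd = wetdays(site.rain, c, log)
    mr = microbial_respiration(soc, site.sand_pct, wd, c, log)
    return FluxBreakdown(
        p_leaf=pl,
        lai=lai,
        anpp_max=amax,
        anpp_est=aest,
        bnpp_est=best,
        pdsoc=pd,
        ddsoc=dd,
        wetdays=wd,
        mresp=mr,
        delta_soc=pd + dd - mr,
    )
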