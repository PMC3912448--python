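"""Model validation against the eight-site Serengeti grazing experiment.

The package ships a transcription of the grazed-plot site means from the
9-year exclosure experiment (eight sites spanning 450-900 mm/yr rainfall,
grazing intensities 0.28-0.69, sandy to silty-clay soils).  Observed SOC
stocks are reconstructed from measured soil %C and bulk density to 40 cm
depth, and compared with the model's equilibrium predictions by ordinary
least squares of observed on predicted, with z-tests of slope = 1 and
intercept = 0.

A plot-level code path (:func:`validate_plot_level`) accepts a user table
of per-plot drivers and observed stocks; per-plot values for the original
experiment were never published, so only the site-level analysis runs on
the packaged fixture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coefficients import CoefficientSet, DomainError, default_coefficients
from .core import SiteConditions
from .dynamics import soc_equilibrium
from .uncertainty import monte_carlo_soc_eq

__all__ = [
    "ExperimentSite",
    "ValidationReport",
    "load_experiment_sites",
    "observed_soc",
    "validate_site_level",
    "validate_plot_level",
    "FIRE_MONITOR_YEARS",
]

#: Years of satellite fire monitoring behind the fixture's fire counts.
FIRE_MONITOR_YEARS = 9

_FIXTURE = "serengeti_sites.csv"
_FIXTURE_SHA256 = "157e5b5880a132c966e6baf262e4888e1a89adcb7c55fd72f5111f807a40a399"


@dataclass(frozen=True)
class ExperimentSite:
    """One experimental site: model drivers plus soil measurements."""

    name: str
    gi: float
    se_gi: float
    ligcell: float
    se_ligcell: float
    rain: float
    se_rain: float
    fires_2000_2008: int
    soil_n_pct: float
    soil_c_pct: float
    soil_p_permil: float
    sand_pct: float
    silt_pct: float
    clay_pct: float
    bulk_density: float

    def __post_init__(self) -> None:
        texture = self.sand_pct + self.silt_pct + self.clay_pct
        if abs(texture - 100.0) > 5.0:
            raise DomainError(
                f"{self.name}: sand+silt+clay = {texture:.1f}, expected ~100"
            )
        if not 0.5 < self.bulk_density < 2.0:
            raise DomainError(
                f"{self.name}: bulk density {self.bulk_density} g/cm3 implausible"
            )
        if not 0 <= self.fires_2000_2008 <= FIRE_MONITOR_YEARS:
            raise DomainError(f"{self.name}: fire count outside monitoring window")

    @property
    def fire(self) -> float:
        """Fire frequency: burns per monitored year."""
        return self.fires_2000_2008 / FIRE_MONITOR_YEARS

    @property
    def conditions(self) -> SiteConditions:
        return SiteConditions(
            rain=self.rain,
            gi=self.gi,
            fire=self.fire,
            ligcell=self.ligcell,
            sand_pct=self.sand_pct,
            name=self.name,
            se_gi=self.se_gi,
            se_ligcell=self.se_ligcell,
            se_rain=self.se_rain,
        )

    @property
    def observed_soc(self) -> float:
        return observed_soc(self.soil_c_pct, self.bulk_density)


def load_experiment_sites() -> list[ExperimentSite]:
    """Load the packaged eight-site fixture (checksum-verified)."""
    raw = (
        resources.files("snapsoc").joinpath("data").joinpath(_FIXTURE).read_bytes()
    )
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"site fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(pd.io.common.BytesIO(raw))
    sites = [
        ExperimentSite(
            name=r["name"],
            gi=r["gi_pct"] / 100.0,
            se_gi=r["se_gi_pct"] / 100.0,
            ligcell=r["ligcell_pct"] / 100.0,
            se_ligcell=r["se_ligcell_pct"] / 100.0,
            rain=float(r["rain"]),
            se_rain=float(r["se_rain"]),
            fires_2000_2008=int(r["fires_2000_2008"]),
            soil_n_pct=r["soil_n_pct"],
            soil_c_pct=r["soil_c_pct"],
            soil_p_permil=r["soil_p_permil"],
            sand_pct=r["sand_pct"],
            silt_pct=r["silt_pct"],
            clay_pct=r["clay_pct"],
            bulk_density=r["bulk_density"],
        )
        for _, r in df.iterrows()
    ]
    if len(sites) != 8:
        raise RuntimeError(f"expected 8 sites, fixture has {len(sites)}")
    return sites


def observed_soc(
    soil_c_pct: float, bulk_density: float, depth_cm: float = 40.0
) -> float:
    """SOC stock (gC/m2) from soil %C and bulk density over ``depth_cm``.

    (C%/100) [gC/g soil] x bulk density [g/cm3] x depth [cm] = gC/cm2,
    times 1e4 cm2/m2.
    """
    if soil_c_pct < 0 or bulk_density <= 0 or depth_cm <= 0:
        raise DomainError("soil %C must be >= 0 and density/depth positive")
    return soil_c_pct / 100.0 * bulk_density * depth_cm * 1.0e4


@dataclass
class ValidationReport:
    """Observed-vs-predicted regression across sites (or plots)."""

    sites: pd.DataFrame  # name, predicted, observed, residual[, mc_sem]
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    z_slope: float
    p_slope: float
    z_intercept: float
    p_intercept: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "r_squared": self.r_squared,
            "z_slope_vs_1": self.z_slope,
            "p_slope_vs_1": self.p_slope,
            "z_intercept_vs_0": self.z_intercept,
            "p_intercept_vs_0": self.p_intercept,
            "sites": self.sites.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _regress(df: pd.DataFrame) -> ValidationReport:
    if df["predicted"].std(ddof=0) == 0:
        raise DomainError("degenerate regression: zero variance in predictions")
    model = sm.OLS(df["observed"], sm.add_constant(df["predicted"])).fit()
    intercept, slope = model.params["const"], model.params["predicted"]
    int_se, slope_se = model.bse["const"], model.bse["predicted"]
    z_slope = (slope - 1.0) / slope_se
    z_int = intercept / int_se
    df = df.assign(residual=model.resid.values)
    return ValidationReport(
        sites=df,
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(int_se),
        r_squared=float(model.rsquared),
        z_slope=float(z_slope),
        p_slope=float(2 * stats.norm.sf(abs(z_slope))),
        z_intercept=float(z_int),
        p_intercept=float(2 * stats.norm.sf(abs(z_int))),
        n=len(df),
    )


def validate_site_level(
    coeffs: CoefficientSet | None = None,
    mc_draws: int = 0,
    seed: int = 0,
) -> ValidationReport:
    """Predict equilibrium SOC for the eight packaged sites and regress the
    reconstructed observed stocks on the predictions.

    With ``mc_draws > 0`` a Monte Carlo standard error is attached per site
    (column ``mc_sem``), propagating coefficient and driver errors.
    """
    c = coeffs or default_coefficients()
    sites = load_experiment_sites()
    rows = []
    for s in sites:
        row = {
            "name": s.name,
            "predicted": soc_equilibrium(s.conditions, c),
            "observed": s.observed_soc,
        }
        if mc_draws > 0:
            row["mc_sem"] = monte_carlo_soc_eq(
                s.conditions, c, n_draws=mc_draws, seed=seed
            ).sem_soc_eq
        rows.append(row)
    return _regress(pd.DataFrame(rows))


def validate_plot_level(
    plots: pd.DataFrame, coeffs: CoefficientSet | None = None
) -> ValidationReport:
    """Observed-vs-predicted regression for a user-supplied per-plot table.

    ``plots`` needs columns ``rain, gi, fire, ligcell, sand_pct`` and
    either ``observed_soc`` or the pair ``soil_c_pct, bulk_density``.
    """
    c = coeffs or default_coefficients()
    rows = []
    for _, r in plots.iterrows():
        site = SiteConditions(
            rain=r["rain"],
            gi=r["gi"],
            fire=r["fire"],
            ligcell=r["ligcell"],
            sand_pct=r["sand_pct"],
            name=str(r.get("name", "")),
        )
        obs = (
            float(r["observed_soc"])
            if "observed_soc" in plots.columns
            else observed_soc(r["soil_c_pct"], r["bulk_density"])
        )
        rows.append(
            {"name": site.name, "predicted": soc_equilibrium(site, c), "observed": obs}
        )
    return _regress(pd.DataFrame(rows))
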