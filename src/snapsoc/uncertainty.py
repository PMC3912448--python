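"""Uncertainty propagation and one-at-a-time sensitivity analysis.

Monte Carlo: every regression coefficient of the model (and, optionally,
each measured site driver with a reported standard error) is drawn
independently from Normal(estimate, SE); the equilibrium SOC is evaluated
per draw and summarized.  Draws that leave the model's domain (a
proportion outside [0, 1], rainfall outside the production-regression
support, no microbially active days) are rejected rather than clipped, so
the retained sample is not distorted toward the boundaries; the retained
count is reported.  Coefficients are sampled independently because no
covariance matrix is available for the underlying regressions - a
documented limitation.

Sensitivity: each of the five drivers is perturbed by +10% at a low,
medium and high level while the other four drivers sit at their own
levels.  The default background policy evaluates the full 3^4 factorial of
the other drivers' levels and reports the mean +/- SE of the absolute
percent change in equilibrium SOC over those backgrounds; a "medium"
policy holds the others at their medium level (a single background).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .coefficients import SAMPLED, CoefficientSet, DomainError, default_coefficients
from .core import SiteConditions
from .dynamics import soc_equilibrium

__all__ = [
    "MonteCarloSummary",
    "monte_carlo_soc_eq",
    "sensitivity_analysis",
    "SENSITIVITY_LEVELS",
]

logger = logging.getLogger(__name__)

#: Low/medium/high driver levels for the one-at-a-time sensitivity design.
SENSITIVITY_LEVELS: dict[str, tuple[float, float, float]] = {
    "rain": (450.0, 650.0, 900.0),
    "fire": (0.25, 0.50, 0.75),
    "gi": (0.25, 0.60, 0.90),
    "ligcell": (0.15, 0.25, 0.35),
    "sand_pct": (25.0, 45.0, 70.0),
}

_LEVEL_NAMES = ("low", "medium", "high")
_PROPORTION_DRIVERS = ("gi", "fire", "ligcell")


@dataclass(frozen=True)
class MonteCarloSummary:
    """Summary of Monte Carlo draws of equilibrium SOC for one site.

    ``sem_soc_eq`` is the standard error of the mean over retained draws
    (sd/sqrt(n_retained)); ``sd_soc_eq`` is the draw standard deviation,
    i.e. the propagated standard error of a single SOC_eq prediction; the
    coefficient of variation is ``cv = sd_soc_eq / mean_soc_eq``.
    """

    site: str
    mean_soc_eq: float
    sem_soc_eq: float
    sd_soc_eq: float
    cv: float
    n_draws: int
    n_retained: int
    seed: int

    @property
    def n_rejected(self) -> int:
        return self.n_draws - self.n_retained


def _draw_coeffs(
    rng: np.random.Generator, coeffs: CoefficientSet
) -> CoefficientSet:
    overrides = {}
    for key in SAMPLED:
        se = coeffs.se(key)
        if se > 0:
            overrides[key] = rng.normal(coeffs[key], se)
    return coeffs.with_values(name=coeffs.name + "-draw", **overrides)


def monte_carlo_soc_eq(
    site: SiteConditions,
    coeffs: CoefficientSet | None = None,
    n_draws: int = 100,
    seed: int = 0,
    sample_coeffs: bool = True,
    sample_drivers: bool = True,
) -> MonteCarloSummary:
    """Propagate coefficient (and driver) errors into equilibrium SOC."""
    c = coeffs or default_coefficients()
    if n_draws < 2:
        raise DomainError(f"n_draws must be >= 2, got {n_draws}")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        try:
            dc = _draw_coeffs(rng, c) if sample_coeffs else c
            if sample_drivers:
                dsite = SiteConditions(
                    rain=rng.normal(site.rain, site.se_rain) if site.se_rain else site.rain,
                    gi=rng.normal(site.gi, site.se_gi) if site.se_gi else site.gi,
                    fire=site.fire,
                    ligcell=(
                        rng.normal(site.ligcell, site.se_ligcell)
                        if site.se_ligcell
                        else site.ligcell
                    ),
                    sand_pct=site.sand_pct,
                    name=site.name,
                )
            else:
                dsite = site
            draws.append(soc_equilibrium(dsite, dc))
        except DomainError:
            continue
    if len(draws) < 2:
        raise DomainError(
            "parameter errors incompatible with model support: "
            f"{len(draws)}/{n_draws} draws retained"
        )
    arr = np.asarray(draws)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return MonteCarloSummary(
        site=site.name or "",
        mean_soc_eq=mean,
        sem_soc_eq=sd / np.sqrt(len(arr)),
        sd_soc_eq=sd,
        cv=sd / mean,
        n_draws=n_draws,
        n_retained=len(arr),
        seed=seed,
    )


def _clip_driver(name: str, value: float) -> tuple[float, bool]:
    if name in _PROPORTION_DRIVERS and value > 1.0:
        return 1.0, True
    if name == "sand_pct" and value > 100.0:
        return 100.0, True
    return value, False


def _soc_eq_at(drivers: dict[str, float], coeffs: CoefficientSet) -> float:
    return soc_equilibrium(
        SiteConditions(
            rain=drivers["rain"],
            gi=drivers["gi"],
            fire=drivers["fire"],
            ligcell=drivers["ligcell"],
            sand_pct=drivers["sand_pct"],
        ),
        coeffs,
    )


def sensitivity_analysis(
    levels: dict[str, tuple[float, float, float]] | None = None,
    perturbation: float = 0.10,
    background: str = "factorial",
    coeffs: CoefficientSet | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of equilibrium SOC to +10% driver changes.

    Returns a 15-row table (5 drivers x 3 levels) with columns
    ``parameter, level, base_value, perturbed_value, mean_abs_pct_change,
    se_abs_pct_change, n_backgrounds``.
    """
    if perturbation <= 0:
        raise DomainError(f"perturbation must be > 0, got {perturbation}")
    if background not in ("factorial", "medium"):
        raise DomainError(f"unknown background policy {background!r}")
    lv = levels or SENSITIVITY_LEVELS
    c = coeffs or default_coefficients()
    names = list(lv)
    n_clipped = 0
    rows = []
    for focal in names:
        others = [n for n in names if n != focal]
        if background == "factorial":
            backgrounds = [
                dict(zip(others, combo))
                for combo in product(*(lv[o] for o in others))
            ]
        else:
            backgrounds = [{o: lv[o][1] for o in others}]
        for level_name, level_value in zip(_LEVEL_NAMES, lv[focal]):
            perturbed, clipped = _clip_driver(focal, level_value * (1 + perturbation))
            if clipped:
                n_clipped += 1
                warnings.warn(
                    f"perturbed {focal} clipped to its valid range", stacklevel=2
                )
            changes = []
            for bg in backgrounds:
                base = _soc_eq_at({**bg, focal: level_value}, c)
                pert = _soc_eq_at({**bg, focal: perturbed}, c)
                changes.append(abs(pert - base) / base * 100.0)
            arr = np.asarray(changes)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            rows.append(
                {
                    "parameter": focal,
                    "level": level_name,
                    "base_value": level_value,
                    "perturbed_value": perturbed,
                    "mean_abs_pct_change": float(arr.mean()),
                    "se_abs_pct_change": float(se),
                    "n_backgrounds": len(arr),
                }
            )
    if n_clipped:
        logger.info("sensitivity analysis clipped %d perturbed values", n_clipped)
    return pd.DataFrame(rows)
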