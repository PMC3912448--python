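"""Re-fitting the model's empirical sub-models from new data.

The SNAP coefficients were estimated from Serengeti field and literature
data.  Transferring the model to another grassland means re-estimating
some of those regressions; this module fits them and writes the estimates
back into a :class:`~snapsoc.coefficients.CoefficientSet` so the full
model runs unchanged on the new coefficients.

The grazing response of leaf area index is the one nonlinear fit:

    LAI = B0 - B1 * exp(B2 * GI),   B1, B2 > 0

(a positive growth rate inside the exponential, so LAI collapses at high
grazing intensity).  Exponential-rate fits are start-sensitive, so the fit
is multi-started over a grid of B2 values and the best sum of squares
wins.  The linear sub-models (leaf proportion, potential production,
water-holding capacity, belowground production, wet-day proportion,
maximum respiration rate) are ordinary least squares.

A synthetic-site generator provides reproducible driver draws for
property tests and scenario studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .coefficients import CoefficientSet, DomainError, default_coefficients
from .core import SiteConditions

__all__ = [
    "LaiFit",
    "LinearFit",
    "fit_lai_response",
    "fit_linear_submodel",
    "generate_synthetic_sites",
    "generate_lai_dataset",
    "ROLE_SLOTS",
    "DEFAULT_SITE_RANGES",
]

#: Linear sub-model roles -> the (intercept, slope) coefficient slots they fill.
ROLE_SLOTS: dict[str, tuple[str, str]] = {
    "p_leaf": ("pl_intercept", "pl_slope"),
    "anpp_max": ("anpp_intercept", "anpp_slope"),
    "whc": ("awhc_intercept", "awhc_slope"),
    "bnpp": ("bnpp_intercept", "bnpp_slope"),
    "wetdays": ("wet_intercept", "wet_slope"),
    "mresp": ("mresp_intercept", "mresp_slope"),
}

#: Driver ranges for synthetic sites, kept inside the model's validity
#: envelope (rainfall well within the production-regression support).
DEFAULT_SITE_RANGES: dict[str, tuple[float, float]] = {
    "rain": (100.0, 1100.0),
    "gi": (0.0, 1.0),
    "fire": (0.0, 1.0),
    "ligcell": (0.10, 0.50),
    "sand_pct": (0.0, 100.0),
}


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / sst


@dataclass(frozen=True)
class LaiFit:
    """Nonlinear LAI-vs-grazing fit: LAI = b0 - b1*exp(b2*GI)."""

    b0: float
    b1: float
    b2: float
    se_b0: float
    se_b1: float
    se_b2: float
    r_squared: float
    converged: bool
    flat: bool  # no grazing signal: b1 ~ 0

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.b0, self.b1, self.b2)


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of one linear sub-model, tagged with its coefficient role."""

    role: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r_squared: float

    def apply(self, coeffs: CoefficientSet | None = None) -> CoefficientSet:
        """Coefficient set with this sub-model's slots replaced."""
        c = coeffs or default_coefficients()
        b0_slot, b1_slot = ROLE_SLOTS[self.role]
        return c.with_values(
            name=f"{c.name}+{self.role}-refit",
            **{b0_slot: self.intercept, b1_slot: self.slope},
        )


def _lai_model(gi, b0, b1, b2):
    return b0 - b1 * np.exp(b2 * gi)


def fit_lai_response(
    gi,
    lai,
    starts: tuple[float, ...] = (1.0, 3.0, 5.0, 8.0),
    seed: int | None = None,
) -> LaiFit:
    """Fit the exponential-collapse LAI response by least squares.

    ``starts`` is the multi-start grid for the exponential rate B2; the
    intercept and amplitude are started at data-driven values.  Raises
    :class:`DomainError` if no start converges.
    """
    gi = np.asarray(gi, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if gi.size < 6:
        raise DomainError(f"need >= 6 points for the 3-parameter fit, got {gi.size}")
    if gi.std() == 0:
        raise DomainError("predictor variance is zero")

    # Flat signal: amplitude indistinguishable from zero.
    if lai.std() < 1e-12:
        return LaiFit(
            b0=float(lai.mean()),
            b1=0.0,
            b2=0.0,
            se_b0=0.0,
            se_b1=0.0,
            se_b2=0.0,
            r_squared=0.0,
            converged=True,
            flat=True,
        )

    best = None
    b0_start = float(lai.max())
    for b2_start in starts:
        amp = max((lai.max() - lai.min()) / max(np.exp(b2_start * gi.max()), 1.0), 1e-6)
        try:
            popt, pcov = curve_fit(
                _lai_model,
                gi,
                lai,
                p0=(b0_start, amp, b2_start),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = lai - _lai_model(gi, *popt)
        sse = float((resid**2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt, pcov, resid)
    if best is None:
        raise DomainError("LAI fit failed to converge from every start")
    _, popt, pcov, resid = best
    ses = np.sqrt(np.diag(pcov))
    flat = abs(popt[1]) < 1e-8
    return LaiFit(
        b0=float(popt[0]),
        b1=float(popt[1]),
        b2=float(popt[2]),
        se_b0=float(ses[0]),
        se_b1=float(ses[1]),
        se_b2=float(ses[2]),
        r_squared=_r_squared(lai, resid),
        converged=True,
        flat=bool(flat),
    )


def fit_linear_submodel(x, y, role: str) -> LinearFit:
    """OLS fit of a linear sub-model (see :data:`ROLE_SLOTS` for roles)."""
    if role not in ROLE_SLOTS:
        raise KeyError(f"unknown sub-model role {role!r}; known: {sorted(ROLE_SLOTS)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise DomainError(f"need >= 4 points for a linear fit, got {x.size}")
    if x.std() == 0:
        raise DomainError("predictor variance is zero (rank-deficient design)")
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    sigma2 = float((resid**2).sum()) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return LinearFit(
        role=role,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(np.sqrt(cov[0, 0])),
        se_slope=float(np.sqrt(cov[1, 1])),
        r_squared=_r_squared(y, resid),
    )


def generate_synthetic_sites(
    n: int,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[SiteConditions]:
    """Draw ``n`` sites with independent uniform drivers, reproducibly.

    Default ranges stay inside the model's validity envelope, so every
    generated site evaluates to a finite equilibrium.
    """
    if n < 0:
        raise DomainError(f"n must be >= 0, got {n}")
    rg = {**DEFAULT_SITE_RANGES, **(ranges or {})}
    for key, (lo, hi) in rg.items():
        if not lo < hi:
            raise DomainError(f"empty or inverted range for {key}: ({lo}, {hi})")
    if not (60.0 <= rg["rain"][0] and rg["rain"][1] <= 1200.0):
        raise DomainError("rain range must lie within (60, 1200) mm/yr")
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n):
        lig_lo, lig_hi = rg["ligcell"]
        sites.append(
            SiteConditions(
                rain=rng.uniform(*rg["rain"]),
                gi=rng.uniform(*rg["gi"]),
                fire=rng.uniform(*rg["fire"]),
                ligcell=rng.uniform(max(lig_lo, 1e-6), min(lig_hi, 0.9499)),
                sand_pct=rng.uniform(*rg["sand_pct"]),
                name=f"synthetic-{i}",
            )
        )
    return sites


def generate_lai_dataset(
    n: int,
    b0: float = 1.15,
    b1: float = 0.015,
    b2: float = 4.6,
    sigma: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (GI, LAI) sample from the exponential-collapse response
    with Gaussian observation noise; for recovery tests and examples."""
    rng = np.random.default_rng(seed)
    gi = rng.uniform(0.0, 1.0, size=n)
    lai = _lai_model(gi, b0, b1, b2) + rng.normal(0.0, sigma, size=n)
    return gi, lai
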