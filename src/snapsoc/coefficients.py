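"""Fitted coefficients of the SNAP model and their standard errors.

Every empirical constant of the model lives in a :class:`CoefficientSet`:
the regression intercepts/slopes of the production, soil-moisture and
respiration sub-models, together with the standard error of each estimate
(zero for fixed constants such as the 240-day season length).  Two named
sets ship with the package:

``text-equations``
    The constants exactly as they appear in the model equations.  This is
    the deterministic default used for point predictions and validation.

``table2-mc``
    The coefficient estimates as reported with the Monte Carlo error
    inventory.  A few values differ slightly from the equation constants
    (e.g. the leaf-proportion intercept 0.597 vs 0.6, belowground
    production 958.8/-0.82 vs 917.4/-0.763); this set is the sampling
    distribution used for uncertainty propagation.

Sets are serializable to a flat text registry (one ``name value se source``
line per coefficient) and reload bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping


class DomainError(ValueError):
    """An input outside the model's domain of validity."""


#: Coefficients re-sampled during Monte Carlo uncertainty propagation.
#: ``lai_b0_fitted`` and the raw WHC entries are carried for reference but
#: do not enter the model evaluation, so they are not sampled.
SAMPLED = (
    "pl_intercept",
    "pl_slope",
    "lai_b1",
    "lai_b2",
    "anpp_intercept",
    "anpp_slope",
    "awhc_intercept",
    "awhc_slope",
    "bnpp_intercept",
    "bnpp_slope",
    "wet_intercept",
    "wet_slope",
    "mresp_intercept",
    "mresp_slope",
    "carbon_frac",
)


@dataclass(frozen=True)
class CoefficientSet:
    """Named collection of (value, standard error, source tag) entries."""

    name: str
    values: Mapping[str, float]
    errors: Mapping[str, float]
    sources: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values) - set(self.errors)
        if missing:
            raise ValueError(f"coefficients without an error entry: {sorted(missing)}")
        for key, se in self.errors.items():
            if not se >= 0:
                raise DomainError(f"standard error of {key!r} must be >= 0, got {se}")
        cf = self.values.get("carbon_frac")
        if cf is not None and not 0 < cf < 1:
            raise DomainError(f"carbon_frac must be in (0, 1), got {cf}")
        sd = self.values.get("season_days")
        if sd is not None and not sd > 0:
            raise DomainError(f"season_days must be > 0, got {sd}")

    def __getattr__(self, key: str) -> float:
        try:
            return self.__dict__["values"][key]
        except KeyError:
            raise AttributeError(key) from None

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def se(self, key: str) -> float:
        """Standard error of the named coefficient."""
        return self.errors[key]

    def source(self, key: str) -> str:
        return self.sources.get(key, "")

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def with_values(self, name: str | None = None, **overrides: float) -> "CoefficientSet":
        """Copy of this set with some coefficient values replaced."""
        unknown = set(overrides) - set(self.values)
        if unknown:
            raise KeyError(f"unknown coefficients: {sorted(unknown)}")
        return replace(
            self,
            name=name or self.name,
            values={**self.values, **overrides},
        )


def _build(name: str, rows: list[tuple[str, float, float, str]]) -> CoefficientSet:
    return CoefficientSet(
        name=name,
        values={r[0]: r[1] for r in rows},
        errors={r[0]: r[2] for r in rows},
        sources={r[0]: r[3] for r in rows},
    )


# Constants as they appear in the model equations; SEs from the error inventory.
_TEXT_ROWS = [
    ("pl_intercept", 0.6, 0.061, "leaf-proportion regression intercept"),
    ("pl_slope", 0.24, 0.023, "leaf-proportion regression slope"),
    ("lai_b1", 0.015, 0.0011, "LAI exponential-decline amplitude"),
    ("lai_b2", 4.6, 0.2, "LAI exponential-decline rate"),
    ("lai_b0_fitted", 1.15, 0.027, "fitted LAI intercept (alternative form)"),
    ("anpp_intercept", -27.5, 17.6, "aboveground production vs rainfall"),
    ("anpp_slope", 0.84, 0.07, "aboveground production vs rainfall"),
    ("awhc_intercept", 1.33, 0.05, "adjusted water-holding-capacity intercept"),
    ("awhc_slope", -0.0075, 0.0008, "adjusted water-holding-capacity slope"),
    ("whc_intercept", 1.04, 0.05, "raw water-holding-capacity intercept"),
    ("whc_slope", -0.0070, 0.0008, "raw water-holding-capacity slope"),
    ("bnpp_intercept", 917.4, 165.0, "belowground production vs rainfall"),
    ("bnpp_slope", -0.763, 0.27, "belowground production vs rainfall"),
    ("wet_intercept", -0.025, 0.033, "wet-day proportion vs rainfall"),
    ("wet_slope", 0.00044, 0.00006, "wet-day proportion vs rainfall"),
    ("season_days", 240.0, 0.0, "wet-season length, days"),
    ("mresp_intercept", -0.579, 0.45, "max daily respiration vs SOC"),
    ("mresp_slope", 0.00044, 0.00007, "max daily respiration vs SOC"),
    ("carbon_frac", 0.45, 0.02, "carbon fraction of plant tissue and dung"),
    ("root_ligcell_offset", 0.05, 0.0, "root lignin+cellulose excess over shoots"),
    ("moisture_threshold", 10.0, 0.0, "gravimetric %water for microbial activity"),
    ("sand_access_base", 0.7, 0.0, "respiration access factor, base"),
    ("sand_access_span", 0.3, 0.0, "respiration access factor, sand span"),
]

_TABLE2_OVERRIDES = {
    "pl_intercept": 0.597,
    "awhc_slope": -0.0070,
    "bnpp_intercept": 958.8,
    "bnpp_slope": -0.82,
    "wet_slope": 0.00043,
    "mresp_intercept": -0.58,
}

TEXT_EQUATIONS = _build("text-equations", _TEXT_ROWS)
TABLE2_MC = _build(
    "table2-mc",
    [(n, _TABLE2_OVERRIDES.get(n, v), se, src) for (n, v, se, src) in _TEXT_ROWS],
)

_NAMED = {s.name: s for s in (TEXT_EQUATIONS, TABLE2_MC)}


def default_coefficients() -> CoefficientSet:
    """The deterministic default coefficient set (``text-equations``)."""
    return TEXT_EQUATIONS


def get_coefficients(name: str) -> CoefficientSet:
    """Look up a shipped coefficient set by name, or load one from a file."""
    if name in _NAMED:
        return _NAMED[name]
    path = Path(name)
    if path.exists():
        return read_registry(path)
    raise KeyError(
        f"unknown coefficient set {name!r}; shipped sets: {sorted(_NAMED)}"
    )


def write_registry(coeffs: CoefficientSet, path: str | Path) -> None:
    """Write a coefficient set as a flat key-value text registry.

    Floats are written with ``repr`` so a round trip is bit-exact.
    """
    lines = [f"# snapsoc coefficient registry", f"# set: {coeffs.name}"]
    for key in coeffs:
        src = coeffs.source(key).replace("\t", " ")
        lines.append(f"{key}\t{coeffs.values[key]!r}\t{coeffs.errors[key]!r}\t{src}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_registry(path: str | Path) -> CoefficientSet:
    """Read a coefficient registry written by :func:`write_registry`."""
    name = Path(path).stem
    values: dict[str, float] = {}
    errors: dict[str, float] = {}
    sources: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# set:"):
                name = line.split(":", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed registry line: {line!r}")
        key, value, se = parts[0], float(parts[1]), float(parts[2])
        values[key] = value
        errors[key] = se
        sources[key] = parts[3] if len(parts) > 3 else ""
    return CoefficientSet(name=name, values=values, errors=errors, sources=sources)
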