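"""Tabular input/output helpers: site tables and self-describing outputs.

Site tables are plain CSV with a mandatory header row; columns
``name, rain, gi, fire, ligcell, sand_pct`` plus optional ``se_gi,
se_ligcell, se_rain``.  Output files written by the CLI carry '#'-prefixed
metadata comment lines (package version, coefficient set, seed, timestamp)
and round-trip through :func:`read_table`.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd

from . import __version__
from .core import SiteConditions

__all__ = ["read_sites_csv", "write_sites_csv", "write_table", "read_table"]

_SE_COLUMNS = ("se_gi", "se_ligcell", "se_rain")


def read_sites_csv(path: str | Path) -> list[SiteConditions]:
    """Read a driver table into :class:`SiteConditions` records."""
    df = pd.read_csv(path, comment="#")
    required = {"rain", "gi", "fire", "ligcell", "sand_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    sites = []
    for i, r in df.iterrows():
        kwargs = {c: float(r[c]) for c in _SE_COLUMNS if c in df.columns and pd.notna(r[c])}
        sites.append(
            SiteConditions(
                rain=float(r["rain"]),
                gi=float(r["gi"]),
                fire=float(r["fire"]),
                ligcell=float(r["ligcell"]),
                sand_pct=float(r["sand_pct"]),
                name=str(r["name"]) if "name" in df.columns else f"site-{i}",
                **kwargs,
            )
        )
    return sites


def write_sites_csv(sites: list[SiteConditions], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "rain": s.rain,
                "gi": s.gi,
                "fire": s.fire,
                "ligcell": s.ligcell,
                "sand_pct": s.sand_pct,
                "se_gi": s.se_gi,
                "se_ligcell": s.se_ligcell,
                "se_rain": s.se_rain,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    coeffs_name: str | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Write a DataFrame as CSV with a self-describing comment header."""
    lines = [f"# snapsoc {__version__}"]
    if coeffs_name is not None:
        lines.append(f"# coefficients: {coeffs_name}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append(f"# written: {_dt.datetime.now(_dt.timezone.utc).isoformat()}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, comment="#")
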