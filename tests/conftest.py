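import pytest

import snapsoc as sp


@pytest.fixture
def coeffs():
    return sp.default_coefficients()


@pytest.fixture
def balanites():
    """Savanna site: moderate grazing, frequent fire, sandy loam."""
    return sp.SiteConditions(
        rain=721.0, gi=0.32, fire=4 / 9, ligcell=0.341, sand_pct=51.0,
        name="Balanites", se_gi=0.14, se_ligcell=0.023, se_rain=86.0,
    )


@pytest.fixture
def barafu():
    """Dry shortgrass-plains site: heavy grazing, rare fire, silty soil."""
    return sp.SiteConditions(
        rain=472.0, gi=0.65, fire=2 / 9, ligcell=0.345, sand_pct=27.6,
        name="Barafu", se_gi=0.04, se_ligcell=0.019, se_rain=31.0,
    )


@pytest.fixture(scope="session")
def random_sites():
    return sp.generate_synthetic_sites(200, seed=42)
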