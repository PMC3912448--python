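"""Unit and property tests for the annual carbon-flux equations."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snapsoc as sp
from snapsoc.coefficients import DomainError

# Tolerances: pure single-equation identities at 1e-9 relative, chained
# worked examples at 1e-3.
EXACT = dict(rel=1e-9)
CHAIN = dict(rel=1e-3)


class TestLeafResponse:
    @pytest.mark.parametrize(
        "gi, expected",
        [(0.0, 0.60), (1.0, 0.84), (0.5, 0.72)],
    )
    def test_proportion_leaf(self, gi, expected):
        assert sp.proportion_leaf(gi) == pytest.approx(expected, **EXACT)

    @pytest.mark.parametrize(
        "gi, expected",
        [(0.0, 0.985), (0.7, 0.9045782), (1.0, 0.0)],
    )
    def test_leaf_area_index(self, gi, expected):
        assert sp.leaf_area_index(gi) == pytest.approx(expected, abs=1e-6)

    def test_lai_clamped_at_extreme_grazing(self):
        # raw value at gi=1 is -0.0923; a leaf area cannot be negative
        raw = (0.6 + 0.24) / 0.6 - 0.015 * math.exp(4.6)
        assert raw < 0
        log = sp.ClampLog()
        assert sp.leaf_area_index(1.0, log=log) == 0.0
        assert log.lai == 1

    @pytest.mark.parametrize("gi", [-0.1, 1.2])
    def test_out_of_range_gi_names_field(self, gi):
        with pytest.raises(DomainError, match="gi"):
            sp.proportion_leaf(gi)
        with pytest.raises(DomainError, match="gi"):
            sp.leaf_area_index(gi)


class TestProduction:
    @pytest.mark.parametrize(
        "sand, expected",
        [(25.0, 1.1425), (44.0, 1.0), (100.0, 0.58)],
    )
    def test_adjusted_whc(self, sand, expected):
        assert sp.adjusted_whc(sand) == pytest.approx(expected, **EXACT)

    def test_adjusted_whc_out_of_range(self):
        with pytest.raises(DomainError, match="sand"):
            sp.adjusted_whc(150.0)

    @pytest.mark.parametrize(
        "rain, sand, expected",
        [(450.0, 25.0, 400.44625), (721.0, 51.0, 547.78765)],
    )
    def test_anpp_max(self, rain, sand, expected):
        assert sp.anpp_max(rain, sand) == pytest.approx(expected, **EXACT)

    def test_anpp_max_refuses_rain_below_support(self):
        with pytest.raises(DomainError, match="rainfall below model support"):
            sp.anpp_max(30.0, 25.0)

    @pytest.mark.parametrize(
        "rain, sand, gi, expected",
        [
            (450.0, 25.0, 0.0, 394.43956),
            (721.0, 51.0, 0.32, 582.09606),
            (450.0, 25.0, 1.0, 0.0),
        ],
    )
    def test_anpp_est(self, rain, sand, gi, expected):
        assert sp.anpp_est(rain, sand, gi) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "rain, expected", [(450.0, 574.05), (721.0, 367.277)]
    )
    def test_bnpp_est(self, rain, expected):
        assert sp.bnpp_est(rain) == pytest.approx(expected, **EXACT)

    def test_bnpp_root_is_support_boundary(self):
        root = 917.4 / 0.763
        assert sp.bnpp_est(root * (1 - 1e-9)) == pytest.approx(0.0, abs=1e-5)
        with pytest.raises(DomainError, match="belowground-production support"):
            sp.bnpp_est(1250.0)


class TestSoilCarbonInputs:
    def test_pdsoc_balanites_chain(self):
        anpp = sp.anpp_est(721.0, 51.0, 0.32)
        bnpp = sp.bnpp_est(721.0)
        pd = sp.plant_derived_soc(anpp, bnpp, 0.32, 4 / 9, 0.341)
        assert pd == pytest.approx(98.366, **CHAIN)

    def test_pdsoc_aboveground_vanishes_with_annual_fire_no_grazing(self):
        pd = sp.plant_derived_soc(500.0, 300.0, 0.0, 1.0, 0.30)
        assert pd == pytest.approx(0.45 * 0.35 * 300.0, **EXACT)

    def test_pdsoc_zero_inputs(self):
        assert sp.plant_derived_soc(0.0, 0.0, 0.2, 0.2, 0.0) == 0.0

    def test_pdsoc_root_fraction_cap(self):
        with pytest.raises(DomainError, match="root offset"):
            sp.plant_derived_soc(100.0, 100.0, 0.2, 0.2, 0.97)

    @pytest.mark.parametrize(
        "anpp, gi, ligcell, expected",
        [
            (582.09606, 0.32, 0.341, 28.583),
            (100.0, 0.0, 0.30, 0.0),
            (100.0, 1.0, 0.30, 13.5),
        ],
    )
    def test_ddsoc(self, anpp, gi, ligcell, expected):
        assert sp.dung_derived_soc(anpp, gi, ligcell) == pytest.approx(
            expected, **CHAIN
        )


class TestMoistureAndRespiration:
    def test_wetdays_threshold_and_examples(self):
        assert sp.wetdays(0.025 / 0.00044) == pytest.approx(0.0, abs=1e-9)
        assert sp.wetdays(50.0) == 0.0  # clamped below threshold rainfall
        assert sp.wetdays(721.0) == pytest.approx(70.1376, **EXACT)
        assert sp.wetdays(472.0) == pytest.approx(43.8432, **EXACT)

    def test_wetdays_never_exceeds_season(self, coeffs):
        assert sp.wetdays(1200.0) <= coeffs.season_days

    def test_mresp_zero_at_respiration_root(self):
        assert sp.microbial_respiration(0.579 / 0.00044, 51.0, 70.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_mresp_balanites_equilibrium_consistency(self):
        # at the site's equilibrium stock, respiration equals total inputs
        assert sp.microbial_respiration(6139.0, 51.0, 70.14) == pytest.approx(
            127.0, **CHAIN
        )

    def test_mresp_zero_wetdays(self):
        assert sp.microbial_respiration(5000.0, 30.0, 0.0) == 0.0

    def test_mresp_clamp_at_low_soc(self):
        log = sp.ClampLog()
        assert sp.microbial_respiration(100.0, 30.0, 50.0, log=log) == 0.0
        assert log.respiration == 1
        # unclamped form (used by the closed-form equilibrium) is negative
        assert sp.microbial_respiration(100.0, 30.0, 50.0, clamp=False) < 0


class TestSiteConditions:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("rain", -10.0),
            ("gi", 1.5),
            ("fire", -0.1),
            ("ligcell", 0.0),
            ("sand_pct", 120.0),
        ],
    )
    def test_invariants_name_offending_field(self, field, value):
        kwargs = dict(rain=500.0, gi=0.3, fire=0.2, ligcell=0.3, sand_pct=40.0)
        kwargs[field] = value
        with pytest.raises(DomainError, match=field.split("_")[0]):
            sp.SiteConditions(**kwargs)

    def test_negative_se_rejected(self):
        with pytest.raises(DomainError, match="se_gi"):
            sp.SiteConditions(
                rain=500.0, gi=0.3, fire=0.2, ligcell=0.3, sand_pct=40.0, se_gi=-1.0
            )


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    rain=st.floats(100.0, 1100.0),
    gi=st.floats(0.0, 1.0),
    fire=st.floats(0.0, 1.0),
    ligcell=st.floats(0.05, 0.6),
    sand=st.floats(0.0, 100.0),
    soc=st.floats(0.0, 20000.0),
)
def test_flux_identity(rain, gi, fire, ligcell, sand, soc):
    """delta_soc = pdsoc + ddsoc - mresp holds to machine precision."""
    site = sp.SiteConditions(rain=rain, gi=gi, fire=fire, ligcell=ligcell, sand_pct=sand)
    fx = sp.evaluate_fluxes(site, soc)
    assert fx.delta_soc == fx.pdsoc + fx.ddsoc - fx.mresp
    assert fx.pdsoc >= 0 and fx.ddsoc >= 0 and fx.wetdays >= 0 and fx.lai >= 0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(gi=st.floats(0.0, 1.0), factor=st.floats(0.5, 2.0))
def test_carbon_fraction_homogeneity(gi, factor):
    """Both soil-carbon inputs scale linearly in the tissue carbon fraction."""
    c = sp.default_coefficients()
    new_cf = min(max(c.carbon_frac * factor, 1e-6), 0.999)
    scaled = c.with_values(carbon_frac=new_cf)
    ratio = new_cf / c.carbon_frac
    site = sp.SiteConditions(rain=600.0, gi=gi, fire=0.3, ligcell=0.3, sand_pct=40.0)
    fx, fx2 = sp.evaluate_fluxes(site, 5000.0, c), sp.evaluate_fluxes(site, 5000.0, scaled)
    assert fx2.pdsoc == pytest.approx(fx.pdsoc * ratio, rel=1e-12)
    assert fx2.ddsoc == pytest.approx(fx.ddsoc * ratio, rel=1e-12)


def test_compensation_hump():
    """Grazer-modified production exceeds the ungrazed potential somewhere
    below 60% grazing and collapses near-total grazing."""
    ratios = {g / 100: sp.anpp_est(600.0, 40.0, g / 100) / sp.anpp_max(600.0, 40.0)
              for g in range(0, 100)}
    assert max(v for g, v in ratios.items() if 0 < g < 0.6) > 1.0
    assert all(v < 0.1 for g, v in ratios.items() if g > 0.97)
    assert ratios[0.99] == 0.0


def test_lai_monotone_decline_beyond_compensation():
    gis = [0.6 + 0.01 * i for i in range(41)]
    vals = [sp.leaf_area_index(g) for g in gis]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestCoefficientRegistry:
    def test_round_trip_bit_exact(self, tmp_path, coeffs):
        path = tmp_path / "coeffs.tsv"
        sp.write_registry(coeffs, path)
        loaded = sp.read_registry(path)
        assert loaded.name == coeffs.name
        for key in coeffs:
            assert loaded.values[key] == coeffs.values[key]
            assert loaded.errors[key] == coeffs.errors[key]

    def test_named_sets(self):
        assert sp.get_coefficients("text-equations") is sp.TEXT_EQUATIONS
        assert sp.get_coefficients("table2-mc") is sp.TABLE2_MC
        with pytest.raises(KeyError):
            sp.get_coefficients("no-such-set")

    def test_mc_set_differs_where_reported(self):
        t, m = sp.TEXT_EQUATIONS, sp.TABLE2_MC
        assert (t.pl_intercept, m.pl_intercept) == (0.6, 0.597)
        assert (t.bnpp_intercept, m.bnpp_intercept) == (917.4, 958.8)
        assert (t.bnpp_slope, m.bnpp_slope) == (-0.763, -0.82)
        assert (t.wet_slope, m.wet_slope) == (0.00044, 0.00043)
        assert t.se("bnpp_intercept") == m.se("bnpp_intercept") == 165.0

    def test_unknown_override_rejected(self, coeffs):
        with pytest.raises(KeyError):
            coeffs.with_values(not_a_coefficient=1.0)
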