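"""Heat Index, Liljegren WBGT, mean radiant temperature, and UTCI with its
validity masking — checked against scalar reference implementations and
published chart/check values."""

import numpy as np
import pytest
from scipy.stats import qmc

from heattract import constants as c
from heattract.heat_indices import (
    direct_beam_fraction,
    heat_index,
    mean_radiant_temperature,
    utci,
    utci_polynomial,
    wbgt_liljegren,
    wind_to_reference_height,
)
from heattract.reconstruction import saturation_vapor_pressure as es
from oracles import (
    liljegren_reference_c,
    mrt_reference_c,
    nws_heat_index_c,
    utci_reference_c,
    wind_2m_reference,
)

SIGMA = c.STEFAN_BOLTZMANN


def lhs_inputs(n, seed=12):
    """Latin-hypercube sample of the warm-season valid input domain.

    GHI is drawn as a clear-sky fraction of the top-of-atmosphere flux for
    the sampled zenith angle, so solar geometry and irradiance stay
    physically consistent (as they are in any zenith-consistent product).
    """
    u = qmc.LatinHypercube(d=7, seed=seed).random(n)
    cza = -1e-4 + (1 + 1e-4) * u[:, 6]
    return {
        "ta": 15 + 30 * u[:, 0],
        "rh": 5 + 95 * u[:, 1],
        "ps": 80_000 + 23_000 * u[:, 2],
        "u10": 0.5 + 14.5 * u[:, 3],
        "ghi": 1100 * u[:, 4] * np.clip(cza, 0.0, 1.0),
        "fdir": 0.9 * u[:, 5],
        "cza": cza,
    }


class TestHeatIndex:
    def test_cool_regime_uses_simple_averaged_formula(self):
        # 15 degC / 50 %: below the 80 degF threshold
        t_f = 15.0 * 1.8 + 32.0
        expected_f = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + 50.0 * 0.094)
        assert heat_index(15.0, 50.0) == pytest.approx((expected_f - 32.0) / 1.8, abs=1e-9)

    @pytest.mark.parametrize(
        "t_f,rh,chart_f",
        [(90.0, 60.0, 100.0), (96.0, 65.0, 121.0), (86.0, 90.0, 105.0)],
    )
    def test_matches_published_chart_within_rounding(self, t_f, rh, chart_f):
        out_f = heat_index((t_f - 32.0) / 1.8, rh) * 1.8 + 32.0
        assert out_f == pytest.approx(chart_f, abs=1.0)

    def test_humidity_monotone_in_hot_regime(self):
        assert heat_index(32.0, 0.0) < heat_index(32.0, 100.0)

    def test_no_masking_anywhere(self):
        combos = heat_index(
            np.array([-10.0, 0.0, 45.0, 45.0]), np.array([0.0, 100.0, 1.0, 100.0])
        )
        assert np.isfinite(combos).all()

    def test_adjustment_regions_match_reference(self):
        # low-RH and high-RH adjustment corners
        for t_f, rh in [(95.0, 5.0), (105.0, 10.0), (82.0, 95.0), (86.0, 99.0)]:
            ta = (t_f - 32.0) / 1.8
            assert heat_index(ta, rh) == pytest.approx(nws_heat_index_c(ta, rh), abs=1e-9)

    def test_oracle_equivalence_on_lhs(self):
        d = lhs_inputs(300, seed=5)
        out = heat_index(d["ta"], d["rh"])
        expect = [nws_heat_index_c(t, r) for t, r in zip(d["ta"], d["rh"])]
        np.testing.assert_allclose(out, expect, atol=0.1)


class TestDirectBeamFraction:
    @pytest.mark.parametrize(
        "ghi,dhi,expected", [(0.5, 0.0, 0.0), (800.0, 200.0, 0.75), (100.0, 150.0, 0.0)]
    )
    def test_examples(self, ghi, dhi, expected):
        assert direct_beam_fraction(ghi, dhi) == pytest.approx(expected)

    def test_clamped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        f = direct_beam_fraction(rng.uniform(0, 1000, 100), rng.uniform(0, 1000, 100))
        assert np.all((f >= 0) & (f <= 1))


class TestWbgtLiljegren:
    def test_weighted_combination(self):
        tw, tg, wbgt = wbgt_liljegren(
            np.array([30.0]), np.array([50.0]), np.array([101325.0]),
            np.array([2.0]), np.array([800.0]), np.array([0.75]), np.array([0.8]),
        )
        assert wbgt[0] == pytest.approx(0.7 * tw[0] + 0.2 * tg[0] + 0.1 * 30.0, abs=1e-12)

    def test_convexity_between_components(self):
        d = lhs_inputs(200, seed=9)
        tw, tg, wbgt = wbgt_liljegren(
            d["ta"], d["rh"], d["ps"], d["u10"], d["ghi"], d["fdir"], d["cza"]
        )
        lo = np.minimum(np.minimum(tw, tg), d["ta"])
        hi = np.maximum(np.maximum(tw, tg), d["ta"])
        assert np.all(wbgt >= lo - 1e-9) and np.all(wbgt <= hi + 1e-9)

    def test_night_globe_cooler_than_day(self):
        common = dict(rh_pct=np.array([60.0]), ps_pa=np.array([101325.0]), u10=np.array([2.0]))
        _, tg_day, _ = wbgt_liljegren(
            np.array([30.0]), common["rh_pct"], common["ps_pa"], common["u10"],
            np.array([800.0]), np.array([0.7]), np.array([0.8]),
        )
        _, tg_night, _ = wbgt_liljegren(
            np.array([30.0]), common["rh_pct"], common["ps_pa"], common["u10"],
            np.array([0.0]), np.array([0.0]), np.array([c.NIGHT_COS_ZENITH_SENTINEL]),
        )
        assert tg_night[0] < tg_day[0]
        assert tg_night[0] < 30.0  # radiates to a cooler sky

    def test_wetbulb_does_not_exceed_air_temperature_at_night(self):
        tw, _, _ = wbgt_liljegren(
            np.array([30.0]), np.array([40.0]), np.array([101325.0]),
            np.array([3.0]), np.array([0.0]), np.array([0.0]),
            np.array([c.NIGHT_COS_ZENITH_SENTINEL]),
        )
        assert tw[0] < 30.0

    def test_oracle_equivalence_on_lhs(self):
        d = lhs_inputs(300, seed=13)
        tw, tg, _ = wbgt_liljegren(
            d["ta"], d["rh"], d["ps"], d["u10"], d["ghi"], d["fdir"], d["cza"]
        )
        for i in range(len(d["ta"])):
            solar = d["ghi"][i] if d["cza"][i] >= c.MIN_COS_ZENITH else 0.0
            u2 = wind_2m_reference(d["u10"][i], solar)
            otw, otg = liljegren_reference_c(
                d["ta"][i], d["rh"][i], d["ps"][i], u2, d["ghi"][i], d["fdir"][i], d["cza"][i]
            )
            assert tw[i] == pytest.approx(otw, abs=0.1)
            assert tg[i] == pytest.approx(otg, abs=0.1)

    def test_wind_profile_conversion_reduces_speed(self):
        u2 = wind_to_reference_height(np.array([5.0, 1.0]), np.array([800.0, 0.0]))
        assert np.all(u2 < np.array([5.0, 1.0]))
        assert np.all(u2 >= c.LILJEGREN.min_speed)


class TestMeanRadiantTemperature:
    def test_isotropic_longwave_equilibrium(self):
        ldown = SIGMA * 300.0**4
        out = mean_radiant_temperature(0.0, 0.0, 0.0, 0.0, ldown, 0.0, 0.0)
        assert out == pytest.approx(300.0 - 273.15, abs=1e-9)

    def test_fourth_root_scaling_of_longwave(self):
        ldown = SIGMA * 300.0**4
        t1 = mean_radiant_temperature(0.0, 0.0, 0.0, 0.0, ldown, 0.0, 0.0) + 273.15
        t2 = mean_radiant_temperature(0.0, 0.0, 0.0, 0.0, 2 * ldown, 0.0, 0.0) + 273.15
        assert t2 / t1 == pytest.approx(2.0 ** 0.25, rel=1e-12)

    def test_all_zero_radiation_is_cold_not_error(self):
        assert mean_radiant_temperature(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0) == -273.15

    def test_oracle_equivalence_on_lhs(self):
        d = lhs_inputs(300, seed=17)
        cz = np.clip(d["cza"], 0.0, 1.0)
        dni = np.where(cz > 0.05, d["ghi"] * d["fdir"] / np.maximum(cz, 0.05), 0.0)
        ldown = 250 + 200 * d["fdir"]
        lnet = -120 + 100 * d["fdir"]
        out = mean_radiant_temperature(
            d["ghi"], 0.8 * d["ghi"], dni, dni * cz, ldown, lnet, cz
        )
        expect = [
            mrt_reference_c(d["ghi"][i], 0.8 * d["ghi"][i], dni[i], dni[i] * cz[i],
                            ldown[i], lnet[i], cz[i])
            for i in range(len(cz))
        ]
        np.testing.assert_allclose(out, expect, atol=0.1)


def utci_boundary_cases():
    """(ta, u10, tmrt, e, expect_valid) spanning every validity limit."""
    e20 = 5.0  # safe vapor pressure at 20 degC (RH ~ 21%)
    return [
        # air-temperature limits
        (-50.0, 1.0, -50.0, 0.03, True),
        (-50.01, 1.0, -50.01, 0.03, False),
        (50.0, 1.0, 50.0, 40.0, True),
        (50.01, 1.0, 50.01, 40.0, False),
        # Tmrt - Ta limits
        (20.0, 1.0, -10.0, e20, True),
        (20.0, 1.0, -10.1, e20, False),
        (20.0, 1.0, 90.0, e20, True),
        (20.0, 1.0, 90.1, e20, False),
        # wind limits
        (20.0, 0.49, 20.0, e20, False),
        (20.0, 0.5, 20.0, e20, True),
        (20.0, 17.0, 20.0, e20, True),
        (20.0, 17.01, 20.0, e20, False),
        # vapor-pressure ceiling (Ta 40: es ~ 73.8 hPa, RH fine)
        (40.0, 1.0, 40.0, 49.9, True),
        (40.0, 1.0, 40.0, 50.0, False),
        # relative-humidity floor (strictly above 5 %)
        (30.0, 1.0, 30.0, 0.049 * es(30.0), False),
        (30.0, 1.0, 30.0, 0.06 * es(30.0), True),
        # non-finite input
        (np.nan, 1.0, 20.0, e20, False),
    ]


class TestUtci:
    def test_published_reference_point(self):
        # operational check value: Ta 25, Tmrt 25, va 1 m/s, RH 50% -> 24.6
        e = 0.5 * es(25.0)
        out = utci(np.array([25.0]), np.array([1.0]), np.array([25.0]), np.array([e]))
        assert out[0] == pytest.approx(24.6, abs=0.05)

    def test_polynomial_matches_scalar_oracle(self):
        d = lhs_inputs(300, seed=23)
        tmrt = d["ta"] + (-20 + 60 * d["fdir"])
        e = np.minimum(45.0, 1 + 44 * d["rh"] / 100.0)
        out = utci_polynomial(d["ta"], d["u10"], tmrt - d["ta"], e / 10.0)
        expect = [
            utci_reference_c(d["ta"][i], d["u10"][i], tmrt[i], e[i]) for i in range(len(e))
        ]
        np.testing.assert_allclose(out, expect, atol=1e-4)

    def test_missingness_is_exactly_the_validity_violations(self):
        cases = utci_boundary_cases()
        ta = np.array([x[0] for x in cases])
        u10 = np.array([x[1] for x in cases])
        tmrt = np.array([x[2] for x in cases])
        e = np.array([x[3] for x in cases])
        expect_valid = np.array([x[4] for x in cases])
        out = utci(ta, u10, tmrt, e)
        np.testing.assert_array_equal(np.isfinite(out), expect_valid)
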