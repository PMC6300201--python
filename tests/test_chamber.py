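"""Closed-chamber total fluxes, Redfield conversion, RQ and light/dark pooling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from benthoflux.chamber import (
    ChamberFluxModel,
    ChamberGeometry,
    FluxResult,
    IncubationSeries,
    carbon_equivalent,
    light_dark_pooling_check,
    nitrate_series,
    respiration_quotient,
    total_flux,
)
from benthoflux.errors import (
    DegenerateSeriesError,
    DomainError,
    InsufficientReplicationError,
)


def make_series(times, concs, geometry, analyte="O2", **kw):
    return IncubationSeries(analyte, tuple(times), tuple(concs), geometry, **kw)


class TestGeometry:
    def test_area_and_volume(self):
        g = ChamberGeometry(19.0, (18.0,))
        assert g.area_m2 == pytest.approx(0.02835, rel=1e-3)
        assert g.volume_l == pytest.approx(5.10, rel=2e-3)

    def test_mean_of_height_readings(self):
        g = ChamberGeometry(19.0, (17.0, 18.0, 19.0))
        assert g.mean_height_cm == pytest.approx(18.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DomainError):
            ChamberGeometry(0.0, (18.0,))
        with pytest.raises(DomainError):
            ChamberGeometry(19.0, ())


class TestTotalFlux:
    def test_hand_evaluated_two_point_uptake(self, chamber_geometry):
        # 30 uM drop over 21 h in the nominal chamber: dC*V/(dt*A) by hand
        res = total_flux(make_series([0, 21], [300, 270], chamber_geometry))
        assert res.value == pytest.approx(-6.17, abs=0.01)
        assert res.uptake == pytest.approx(6.17, abs=0.01)
        assert res.qc == "ok"

    def test_zero_change_flagged_below_detection(self, chamber_geometry):
        res = total_flux(make_series([0, 21], [300.0, 300.0], chamber_geometry))
        assert res.value == 0.0
        assert res.qc == "below_detection"

    def test_dic_detection_limit(self, chamber_geometry):
        res = total_flux(make_series([0, 21], [2050.0, 2050.04], chamber_geometry, analyte="DIC"))
        assert res.qc == "below_detection"

    def test_noiseless_multipoint_recovers_imposed_flux(self, chamber_geometry):
        true_flux = 12.5  # mmol m-2 d-1 efflux
        times = np.linspace(0, 21, 5)
        rate = true_flux * chamber_geometry.area_m2 / chamber_geometry.volume_l * 1000 / 24
        concs = 100 + rate * times
        res = total_flux(make_series(times, concs, chamber_geometry))
        assert res.value == pytest.approx(true_flux, rel=1e-9)
        assert res.qc == "ok" and res.slope_p < 1e-6

    def test_constant_multipoint_flagged_nonsignificant(self, chamber_geometry):
        res = total_flux(make_series([0, 7, 14, 21], [50.0] * 4, chamber_geometry))
        assert res.value == 0.0
        assert res.qc == "nonsignificant_slope"

    def test_noisy_flat_series_flagged(self, chamber_geometry, rng):
        concs = 100 + 0.5 * rng.standard_normal(6)
        res = total_flux(make_series(np.linspace(0, 21, 6), concs, chamber_geometry))
        assert res.qc == "nonsignificant_slope"

    def test_zero_time_span_rejected(self, chamber_geometry):
        with pytest.raises(DegenerateSeriesError):
            make_series([5, 5], [1, 2], chamber_geometry)

    @given(
        dc=st.floats(-50, 50),
        height=st.floats(5, 50),
        dt=st.floats(1, 48),
    )
    def test_linearity_in_concentration_volume_and_time(self, dc, height, dt):
        g = ChamberGeometry(19.0, (height,))
        res = total_flux(make_series([0, dt], [300, 300 + dc], g, detection_limit=0.0))
        expected = dc * g.volume_l / (dt * g.area_m2) * 24 / 1000
        assert res.value == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @given(dc=st.floats(0.5, 100))
    def test_sign_convention_round_trip(self, dc, ):
        g = ChamberGeometry(19.0, (18.0,))
        down = total_flux(make_series([0, 21], [300, 300 - dc], g, detection_limit=0.0))
        up = total_flux(make_series([0, 21], [300, 300 + dc], g, detection_limit=0.0))
        assert down.value < 0 < up.value
        assert down.value == pytest.approx(-up.value, rel=1e-9)

    def test_model_summary_mentions_qc(self, chamber_geometry):
        res = ChamberFluxModel(make_series([0, 21], [300, 270], chamber_geometry)).fit()
        assert "qc=ok" in res.summary()


class TestNitrateDerivation:
    def test_pointwise_subtraction(self, chamber_geometry):
        nox = make_series([0, 21], [25.3, 22.0], chamber_geometry, analyte="NOx")
        no2 = make_series([0, 21], [0.3, 0.4], chamber_geometry, analyte="NO2")
        no3 = nitrate_series(nox, no2)
        assert no3.analyte == "NO3"
        assert no3.concentrations == pytest.approx((25.0, 21.6))

    def test_grid_mismatch_rejected(self, chamber_geometry):
        nox = make_series([0, 21], [25.0, 22.0], chamber_geometry, analyte="NOx")
        no2 = make_series([0, 20], [0.3, 0.4], chamber_geometry, analyte="NO2")
        with pytest.raises(DegenerateSeriesError):
            nitrate_series(nox, no2)


class TestCarbonEquivalent:
    @pytest.mark.parametrize("tou,expected", [(33.0, 25.0), (43.0, 33.0)])
    def test_printed_site_values_round_trip(self, tou, expected):
        assert round(carbon_equivalent(tou)) == expected

    def test_zero(self):
        assert carbon_equivalent(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            carbon_equivalent(-1.0)


def flux(value, qc="ok", analyte="O2"):
    return FluxResult(value=value, analyte=analyte, method="total", qc=qc)


class TestRespirationQuotient:
    def test_equal_magnitudes_give_unity(self):
        assert respiration_quotient(flux(5.0, analyte="DIC"), flux(-5.0)) == pytest.approx(1.0)

    def test_site_like_values(self):
        assert respiration_quotient(flux(18.2, analyte="DIC"), flux(-33.0)) == pytest.approx(
            0.55, abs=0.005
        )

    def test_zero_oxygen_flux_rejected(self):
        with pytest.raises(DomainError):
            respiration_quotient(flux(5.0, analyte="DIC"), flux(0.0))

    def test_flagged_inputs_warn(self):
        with pytest.warns(UserWarning):
            respiration_quotient(flux(5.0, qc="below_detection", analyte="DIC"), flux(-10.0))


class TestLightDarkPooling:
    def test_identical_groups_poolable_with_p_one(self):
        res = light_dark_pooling_check([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.poolable and res.p == 1.0

    def test_separated_groups_not_poolable(self):
        res = light_dark_pooling_check([1, 2, 3], [101, 102, 103])
        assert not res.poolable

    def test_insufficient_replication_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            light_dark_pooling_check([1.0], [2.0, 3.0])

    def test_size_under_null_at_analyte_noise(self, rng):
        """Equal-mean groups at n=3 pool in ~95% of simulations (test size ~5%)."""
        poolable = 0
        n_sim = 500
        for _ in range(n_sim):
            a = 10 + 0.15 * rng.standard_normal(3)
            b = 10 + 0.15 * rng.standard_normal(3)
            poolable += light_dark_pooling_check(a, b).poolable
        assert poolable / n_sim >= 0.90
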