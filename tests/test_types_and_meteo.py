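"""Container invariants and psychrometric identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ideovine import meteo
from ideovine.types import GenotypeTraits, PhenologyCalendar, PVSeries, VulnerabilityCurve


class TestVulnerabilityCurve:
    @given(
        p50=st.floats(-6.0, -0.5),
        slope=st.floats(10.0, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_p12_p50_p88_ordering_and_midpoint(self, p50, slope):
        c = VulnerabilityCurve(p50=p50, slope=slope)
        assert c.p88 < c.p50 < c.p12
        assert c.pep(p50) == pytest.approx(50.0)

    def test_closed_form_offsets_at_slope_50(self):
        c = VulnerabilityCurve(p50=-1.5, slope=50.0)
        assert c.p12 - c.p50 == pytest.approx(1.0)
        assert c.p88 - c.p50 == pytest.approx(-1.0)

    def test_monotone_non_increasing_in_psi(self):
        c = VulnerabilityCurve(p50=-2.0, slope=60.0)
        psi = np.linspace(-6, 0, 200)
        assert np.all(np.diff(c.pep(psi)) <= 0)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            VulnerabilityCurve(p50=-1.0, slope=-5.0)


class TestGenotypeTraits:
    def test_derived_fields_satisfy_closed_forms(self):
        t = GenotypeTraits.from_measured(
            "x", gc_max=200.0, pgs50=-0.8, gs_slope=5.0, g_night=15.0,
            g_min=3.0, pi0=-1.0, epsilon=10.0, p50_leaf=-2.0, plc_slope=60.0,
        )
        assert t.psi_gs90 == pytest.approx(-0.8 - np.log(9) / 5.0)
        assert t.psi_tlp == pytest.approx(-1.0 * 10.0 / (-1.0 + 10.0))
        assert t.hsm_p50 == pytest.approx(t.psi_gs90 - t.p50_leaf)
        assert t.hsm_p12 == pytest.approx(t.psi_gs90 - t.p12_leaf)
        # sigmoid midpoint: half of maximal opening at Pgs50
        assert t.closure_fraction(t.pgs50) == pytest.approx(0.5)

    def test_inconsistent_hsm_rejected(self):
        t = GenotypeTraits.from_measured(
            "x", gc_max=200.0, pgs50=-0.8, gs_slope=5.0, g_night=15.0,
            g_min=3.0, pi0=-1.0, epsilon=10.0, p50_leaf=-2.0, plc_slope=60.0,
        )
        bad = t.to_dict()
        bad["hsm_p50"] = bad["hsm_p50"] + 0.5
        with pytest.raises(ValueError):
            GenotypeTraits(**bad)

    def test_conductance_ordering_enforced(self):
        with pytest.raises(ValueError):
            GenotypeTraits.from_measured(
                "x", gc_max=10.0, pgs50=-0.8, gs_slope=5.0, g_night=15.0,
                g_min=3.0, pi0=-1.0, epsilon=10.0, p50_leaf=-2.0, plc_slope=60.0,
            )


class TestPVSeries:
    def test_rwc_and_validation(self):
        pv = PVSeries(
            psi_leaf=[-0.2, -0.5, -1.0],
            mass=[1.9, 1.7, 1.5],
            turgid_weight=2.0,
            dry_weight=0.5,
        )
        assert pv.rwc[0] == pytest.approx((1.9 - 0.5) / 1.5 * 100)
        with pytest.raises(ValueError):
            PVSeries(psi_leaf=[-0.5, -0.2], mass=[1.7, 1.9],
                     turgid_weight=2.0, dry_weight=0.5)


class TestMeteo:
    def test_kg_route_matches_molar_ficks_law(self):
        """With the ideal-gas K_G, the mass-unit conductance route equals
        the molar route Gc = E * P / D."""
        e = 2.0  # mmol m-2 s-1
        for t_c in (10.0, 25.0, 35.0):
            gc_kg = meteo.conductance_from_flux(e, t_c, 60.0)
            gc_molar = e * meteo.P_ATM / float(meteo.vpd(t_c, 60.0))
            assert gc_kg == pytest.approx(gc_molar, rel=2e-3)

    def test_flux_conductance_round_trip(self):
        gc = 150.0
        e = meteo.flux_from_conductance(gc, 25.0, 55.0)
        assert meteo.conductance_from_flux(e, 25.0, 55.0) == pytest.approx(gc)

    def test_rh_zero_rejected(self):
        with pytest.raises(ValueError):
            meteo.vpd(25.0, 0.0)


class TestPhenology:
    def test_lai_ramp_and_defoliation(self):
        cal = PhenologyCalendar()
        assert cal.lai(100) == 0.0
        assert cal.lai(140) == pytest.approx(1.5)
        assert cal.lai(130) == pytest.approx(0.75)
        assert cal.lai(300) == 0.0
        doy = np.arange(1, 366)
        lai = cal.lai(doy)
        assert lai.max() == pytest.approx(1.5)
        assert np.all(lai >= 0)
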