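"""Trait derivation from raw phenotyping streams."""

import numpy as np
import pytest

from ideovine import meteo
from ideovine.traits import (
    FitError,
    analyze_pv_curve,
    estimate_gmin,
    fit_gc_response,
    fit_vulnerability_curve,
    gc_sigmoid,
    leaf_area_allometry,
    pep_sigmoid,
    transpiration_and_conductance,
)
from ideovine.types import LysimeterSeries, PVSeries


def _series(time, weight, t_c=25.0, rh=60.0, ppfd=1000.0, **kw):
    n = len(time)
    return LysimeterSeries(
        time=time, weight=weight,
        air_temp=np.full(n, t_c), rh=np.full(n, rh), ppfd=np.full(n, ppfd), **kw
    )


class TestTranspiration:
    def test_constant_weight_gives_zero_flux(self):
        t = np.arange(0, 7200, 600.0)
        out = transpiration_and_conductance(_series(t, np.full(t.size, 5000.0)), leaf_area=0.5)
        assert np.allclose(out["e"], 0.0)
        assert np.allclose(out["gc"], 0.0)

    def test_known_weight_rate_arithmetic(self):
        # dW/dt = -1.8e-3 g/s over 1 m2 -> E = 0.1 mmol m-2 s-1
        t = np.arange(0, 7200, 600.0)
        w = 5000.0 - 1.8e-3 * t
        out = transpiration_and_conductance(_series(t, w), leaf_area=1.0)
        assert np.allclose(out["e"].iloc[1:-1], 0.1, rtol=1e-9)

    def test_gc_recovered_from_forward_simulated_weight_loss(self):
        """Weight loss forward-simulated from a known Gc(t) via the same
        VPD/K_G relations inverts to within 1%."""
        t = np.arange(0, 6 * 3600, 300.0)
        gc_true = 150.0 + 50.0 * np.sin(t / 8000.0)
        e = meteo.flux_from_conductance(gc_true, 25.0, 60.0)  # mmol m-2 s-1
        leaf_area = 0.4
        loss = np.cumsum(e) * 300.0 * 1e-3 * meteo.MW_WATER * leaf_area
        out = transpiration_and_conductance(_series(t, 6000.0 - loss), leaf_area, window_s=600.0)
        mid = slice(4, -4)
        assert np.allclose(out["gc"].to_numpy()[mid], gc_true[mid], rtol=0.01)

    def test_light_filter_masks_low_ppfd(self):
        t = np.arange(0, 3600, 600.0)
        s = _series(t, 5000.0 - 0.01 * t, ppfd=200.0)
        out = transpiration_and_conductance(s, leaf_area=0.5)
        assert out["gc"].isna().all()
        assert not out["e"].isna().any()

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            _series(np.array([0.0, 10.0, 5.0]), np.array([1.0, 1.0, 1.0]))


class TestGcResponseFit:
    def test_noise_free_recovery_to_four_significant_digits(self):
        psi = np.linspace(-2.0, -0.05, 25)
        gc = gc_sigmoid(psi, 300.0, 5.0, -0.8)
        fit = fit_gc_response(gc, psi)
        assert fit.gsm == pytest.approx(300.0, rel=1e-4)
        assert fit.slp == pytest.approx(5.0, rel=1e-4)
        assert fit.pgs50 == pytest.approx(-0.8, rel=1e-4)

    def test_midpoint_and_gs90_closed_form(self):
        psi = np.linspace(-2.5, -0.05, 30)
        fit = fit_gc_response(gc_sigmoid(psi, 250.0, 6.0, -0.9), psi)
        assert fit.predict(fit.pgs50) == pytest.approx(0.5 * fit.gsm)
        assert fit.psi_gs90 - fit.pgs50 == pytest.approx(-np.log(9.0) / fit.slp)
        # 90% closure: Gc at psi_gs90 is 10% of gsm
        assert fit.predict(fit.psi_gs90) == pytest.approx(0.1 * fit.gsm, rel=1e-6)

    def test_unbiased_under_gaussian_noise(self):
        """Mean fitted Pgs50 over 200 seeded replicates stays within
        SD/sqrt(n) of truth."""
        rng = np.random.default_rng(99)
        psi = np.linspace(-2.0, -0.05, 40)
        truth = (300.0, 5.0, -0.8)
        sd = 10.0
        est = []
        for _ in range(200):
            gc = gc_sigmoid(psi, *truth) + rng.normal(0, sd, psi.size)
            est.append(fit_gc_response(gc, psi).pgs50)
        est = np.asarray(est)
        assert abs(est.mean() - truth[2]) < est.std(ddof=1) / np.sqrt(est.size) * 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gc_response(np.array([1.0, 2.0]), np.array([-1.0, -0.5]))


class TestPVCurve:
    @staticmethod
    def _pv(pi0, eps, n=18, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x_tlp = -pi0 / eps
        x = np.linspace(0.02, 2.3 * x_tlp, n)
        psi = np.maximum(-pi0 - eps * x, 0.0) + pi0 / (1.0 - x)
        mass = 0.4 + 1.6 * (1.0 - x) + rng.normal(0, noise, n)
        return PVSeries(psi_leaf=psi, mass=mass, turgid_weight=2.0, dry_weight=0.4)

    def test_tlp_matches_closed_form(self):
        res = analyze_pv_curve(self._pv(-1.0, 10.0))
        assert res.psi_tlp == pytest.approx(-1.0 * 10.0 / (10.0 - 1.0), abs=0.02)
        assert res.pi0 == pytest.approx(-1.0, abs=0.01)
        assert res.epsilon == pytest.approx(10.0, rel=0.02)

    def test_fully_hydrated_point_excluded_from_fit(self):
        """A Psi = 0 point (divergent -1/Psi) must not poison the analysis."""
        pv = self._pv(-1.2, 12.0)
        pv2 = PVSeries(
            psi_leaf=np.concatenate([[-1e-12], pv.psi_leaf]),
            mass=np.concatenate([[2.0], pv.mass]),
            turgid_weight=2.0, dry_weight=0.4,
        )
        res = analyze_pv_curve(pv2)
        assert np.isfinite(res.psi_tlp)
        assert res.pi0 == pytest.approx(-1.2, abs=0.02)

    @pytest.mark.parametrize("pi0,eps", [(-0.8, 8.0), (-1.2, 14.0), (-1.5, 9.0)])
    def test_pi0_less_negative_than_tlp(self, pi0, eps):
        res = analyze_pv_curve(self._pv(pi0, eps))
        assert res.pi0 > res.psi_tlp

    def test_too_few_post_tlp_points_rejected(self):
        with pytest.raises(ValueError):
            analyze_pv_curve(self._pv(-1.0, 10.0, n=6), min_post_tlp=5)


class TestGmin:
    def test_zero_mass_loss_gives_zero_gmin(self):
        t = np.arange(0, 7200, 600.0)
        res = estimate_gmin(t, np.full(t.size, 1.8), vpd_kpa=1.5, leaf_area_m2=0.004)
        assert res.g_min == 0.0

    def test_hand_arithmetic(self):
        # E = 0.5 mmol m-2 s-1, D = 1.5 kPa, P = 101.325 -> gmin = E P / D
        area = 0.004
        t = np.arange(0, 7200, 600.0)
        slope = -0.5 * 1e-3 * meteo.MW_WATER * area  # g/s
        res = estimate_gmin(t, 1.8 + slope * t, vpd_kpa=1.5, leaf_area_m2=area, patm_kpa=101.325)
        assert res.g_min == pytest.approx(0.5 * 101.325 / 1.5, rel=1e-6)
        assert res.g_min == pytest.approx(33.775, rel=1e-3)

    def test_no_steady_segment_reports_candidates(self):
        t = np.arange(0, 7200, 600.0)
        m = 2.0 - 1e-4 * t + 5e-9 * t**2  # strongly curved throughout
        with pytest.raises(ValueError, match="candidate windows"):
            estimate_gmin(t, m, vpd_kpa=1.5, leaf_area_m2=0.004, r2_min=0.999999)


class TestVulnerabilityFit:
    def test_noise_free_exact_recovery(self):
        psi = np.linspace(-3.5, -0.2, 30)
        curve, p12, p88 = fit_vulnerability_curve(pep_sigmoid(psi, -1.5, 60.0), psi)
        assert curve.p50 == pytest.approx(-1.5, rel=1e-4)
        assert curve.slope == pytest.approx(60.0, rel=1e-4)
        assert p12 == pytest.approx(50.0 / 60.0 - 1.5)
        assert p88 == pytest.approx(-50.0 / 60.0 - 1.5)

    def test_flat_pep_rejected(self):
        psi = np.linspace(-3, -1, 10)
        with pytest.raises(ValueError):
            fit_vulnerability_curve(np.full(10, 40.0), psi)


class TestAllometry:
    def test_power_law_exact_recovery(self):
        length = np.linspace(2.0, 15.0, 40)
        model = leaf_area_allometry(length, 1.0 * length**2)
        assert model.kind == "power"
        assert model.a == pytest.approx(1.0, rel=1e-9)
        assert model.b == pytest.approx(2.0, rel=1e-9)
        assert model.predict(0.0) == 0.0

    def test_prediction_monotone_in_length(self):
        rng = np.random.default_rng(3)
        length = rng.uniform(2, 15, 60)
        area = 0.5 * length**1.8 * np.exp(rng.normal(0, 0.05, 60))
        model = leaf_area_allometry(length, area)
        grid = np.linspace(0.1, 20, 100)
        assert np.all(np.diff(model.predict(grid)) > 0)

    def test_negative_length_rejected(self):
        model = leaf_area_allometry(np.linspace(1, 10, 12), np.linspace(1, 10, 12))
        with pytest.raises(ValueError):
            model.predict(np.array([-1.0]))
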