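"""Soil-plant network physics: stomata, embolism, equilibria, assimilation."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ideovine.photosynthesis import FarquharParams, _arrhenius, electron_transport, net_assimilation
from ideovine.simulator import (
    DiurnalForcing,
    PlantArchitecture,
    SimConfig,
    Simulation,
    simulate_to_failure,
    standard_forcing,
    stomatal_conductance,
    traits_frame,
    update_plc,
    vineyard_architecture,
)
from ideovine.soil import pot_profile
from ideovine.types import GenotypeTraits, VulnerabilityCurve


def make_traits(**kw):
    base = dict(
        name="t", gc_max=200.0, pgs50=-0.8, gs_slope=5.0, g_night=15.0,
        g_min=3.0, pi0=-1.0, epsilon=10.0, p50_leaf=-2.0, plc_slope=60.0,
    )
    base.update(kw)
    return GenotypeTraits.from_measured(**base)


class TestStomatalConductance:
    def test_open_at_hydration_closed_at_drought(self):
        t = make_traits()
        assert stomatal_conductance(-0.01, t, ppfd=1500.0) == pytest.approx(t.gc_max, rel=0.02)
        assert stomatal_conductance(-5.0, t, ppfd=1500.0) == t.g_min

    def test_half_closure_at_pgs50(self):
        t = make_traits()
        assert t.gc_max * t.closure_fraction(t.pgs50) == pytest.approx(0.5 * t.gc_max)

    def test_night_uses_gnight_with_same_regulation(self):
        t = make_traits()
        assert stomatal_conductance(-0.01, t, ppfd=0.0) == pytest.approx(t.g_night, rel=0.02)
        assert stomatal_conductance(-5.0, t, ppfd=0.0) == t.g_min


class TestUpdatePlc:
    CURVE = VulnerabilityCurve(p50=-2.0, slope=100.0)

    def test_negligible_above_p12(self):
        assert update_plc(-0.5, self.CURVE, 0.0) < 1.0

    def test_midpoint(self):
        assert update_plc(self.CURVE.p50, self.CURVE, 0.0) == pytest.approx(50.0)

    def test_irreversible_under_oscillating_psi(self):
        plc = 0.0
        seen = []
        for psi in [-2.0, -1.0, -2.0, -1.5, -2.2, -1.0]:
            plc = float(update_plc(psi, self.CURVE, plc))
            seen.append(plc)
        assert np.all(np.diff(seen) >= 0)
        # brute-force: the running maximum of the instantaneous curve
        expect = np.maximum.accumulate(
            [float(self.CURVE.pep(p)) for p in [-2.0, -1.0, -2.0, -1.5, -2.2, -1.0]]
        )
        assert np.allclose(seen, expect)

    def test_invalid_previous_plc_rejected(self):
        with pytest.raises(ValueError):
            update_plc(-1.0, self.CURVE, 130.0)


def _closed_system_sim(traits, water_l=50.0, **arch_kw):
    layers, depths = pot_profile(water_capacity_l=water_l, leaf_area=1.0)
    kw = dict(
        k_root=1e-9, k_stem_leaf=500.0, k_leaf_sym=500.0,
        c_stem=1e-6, c_leaf_apo=1e-6, v_cav_reservoir=0.0,
        g_bl_leaf=1e7, g_bl_canopy=1e7,
    )
    kw.update(arch_kw)
    arch = PlantArchitecture(soil_layers=layers, layer_depth_mm=depths, **kw)
    cfg = SimConfig(energy_balance=False, dpsi_max=1.0)
    return Simulation(traits_frame(traits), arch, cfg)


class TestStep:
    def test_equilibrium_is_a_fixed_point(self):
        """Saturated air (zero VPD) and equilibrated potentials: nothing moves."""
        t = make_traits(p50_leaf=-8.0, plc_slope=100.0, pgs50=-6.0)
        sim = _closed_system_sim(t, k_root=500.0)
        before = (sim.psi_ls.copy(), sim.psi_stem.copy(), sim.theta.copy(), sim.plc.copy())
        for _ in range(5):
            sim.advance(20.0, 100.0, 0.0, 600.0)
        assert np.allclose(sim.psi_ls, before[0], atol=1e-10)
        assert np.allclose(sim.psi_stem, before[1], atol=1e-10)
        assert np.allclose(sim.theta, before[2], atol=1e-14)
        assert np.allclose(sim.plc, before[3], atol=1e-10)

    def test_water_mass_conserved_over_two_days(self):
        t = make_traits()
        sim = Simulation(traits_frame(t), vineyard_architecture())
        sim.run(standard_forcing(), days=2, dt=600.0)
        assert sim.conservation_residual()[0] < 1e-9

    def test_plc_never_decreases_within_a_run(self, grenache):
        sim = Simulation(traits_frame(grenache), vineyard_architecture(taw_mm=40.0))
        rec = sim.run(standard_forcing(), days=40, dt=1200.0, record_every=43200.0)
        plc = rec.sort_values("clock_s")["plc_leaf"].to_numpy()
        assert np.all(np.diff(plc) >= -1e-12)


class TestAssimilation:
    def test_closed_stomata_respire_only(self):
        a = net_assimilation(ppfd=1500.0, t_leaf=25.0, gs_mmol=0.0, co2=400.0)
        assert a <= 0.0

    def test_dark_returns_respiration(self):
        p = FarquharParams()
        a = net_assimilation(ppfd=0.0, t_leaf=25.0, gs_mmol=100.0, co2=400.0, params=p)
        assert a == pytest.approx(-p.rd25, rel=1e-6)

    def test_co2_fertilisation_direction(self):
        a400 = net_assimilation(1200.0, 25.0, 150.0, 400.0)
        a700 = net_assimilation(1200.0, 25.0, 150.0, 700.0)
        assert a700 > a400

    @pytest.mark.parametrize("gs,t_leaf,ppfd,co2", [
        (150.0, 25.0, 1500.0, 400.0),
        (40.0, 35.0, 800.0, 550.0),
        (300.0, 15.0, 300.0, 400.0),
    ])
    def test_against_bisection_on_supply_demand(self, gs, t_leaf, ppfd, co2):
        """Independent root-finding on the supply-demand intersection."""
        p = FarquharParams()
        gc = gs / 1.6 / 1e3
        vc = _arrhenius(p.vcmax25, p.ea_vcmax, t_leaf)
        jm = _arrhenius(p.jmax25, p.ea_jmax, t_leaf)
        rd = _arrhenius(p.rd25, p.ea_rd, t_leaf)
        kc = _arrhenius(p.kc25, p.ea_kc, t_leaf)
        ko = _arrhenius(p.ko25, p.ea_ko, t_leaf)
        gam = _arrhenius(p.gamma_star25, p.ea_gamma, t_leaf)
        km = kc * (1 + p.o2 / ko)
        j = electron_transport(ppfd, jm, p.alpha_q, p.theta_j)

        def demand(ci):
            return min(vc * (ci - gam) / (ci + km), j / 4 * (ci - gam) / (ci + 2 * gam)) - rd

        ci = brentq(lambda c: gc * (co2 - c) - demand(c), 1e-6, co2 * 3)
        expected = gc * (co2 - ci)
        got = float(net_assimilation(ppfd, t_leaf, gs, co2, p))
        assert got == pytest.approx(expected, rel=1e-6)


class TestSimulateToFailure:
    def test_no_residual_loss_never_fails(self):
        t = make_traits(g_min=0.0, g_night=0.0, pgs50=-0.02, gs_slope=60.0)
        d = simulate_to_failure(t, dt=1200.0, horizon_days=5.0)
        assert d == math.inf

    def test_doubling_gcmax_accelerates_failure(self):
        import pandas as pd

        base = traits_frame(make_traits()).iloc[0].to_dict()
        fast = dict(base, gc_max=2 * base["gc_max"])
        days = simulate_to_failure(
            pd.DataFrame([base, fast]), arch=vineyard_architecture(taw_mm=40.0),
            dt=1200.0, horizon_days=120.0,
        )
        assert days[1] < days[0]


class TestDefaultParameterFile:
    def test_packaged_defaults_match_constructors(self):
        """The shipped parameter file and the dataclass defaults agree."""
        from ideovine.simulator import load_default_parameters
        from ideovine.soil import DEFAULT_TEXTURE

        cfg = load_default_parameters()
        arch = vineyard_architecture()
        for key, val in cfg["architecture"].items():
            assert getattr(arch, key) == pytest.approx(val), key
        for key in ("theta_sat", "theta_res", "alpha", "n_vg"):
            assert DEFAULT_TEXTURE[key] == pytest.approx(cfg["soil"][key]), key
        forcing = standard_forcing()
        for key in ("t_day", "rh_day", "ppfd_day", "t_night", "rh_night", "photoperiod_h", "co2"):
            assert getattr(forcing, key) == pytest.approx(cfg["forcing"][key]), key
        sim_cfg = SimConfig()
        assert sim_cfg.dt == cfg["numerics"]["dt"]
        assert sim_cfg.failure_plc == cfg["numerics"]["failure_plc"]
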