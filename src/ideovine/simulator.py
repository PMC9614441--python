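"""Discrete-time soil-plant hydraulic network ("SurEau-lite").

The plant is a chain of variable conductances and capacitances: three soil
layers (Van Genuchten retention) feed a stem node through root conductances;
the stem feeds the leaf apoplasm (xylem, conductance scaled by 1 - PLC/100)
which feeds the leaf symplasm, from which transpiration leaves at a rate set
by stomatal closure, the cuticular minimum conductance and two boundary
layers in series.  Leaf temperature follows a linearised isothermal
net-radiation energy balance; embolism is irreversible between resets and
returns its water to the transpiration stream.

Integration is a backward-Euler solve of the three plant nodes with
transpiration linearised in leaf water potential and adaptive sub-stepping;
soil stocks are updated explicitly from the same discrete fluxes, so water
mass is conserved by construction.  All per-area quantities are per m2 of
leaf area; fluxes in mmol m-2 s-1, potentials in MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .meteo import (
    CP_MOL,
    LAMBDA_MOL,
    P_ATM,
    SIGMA_SB,
    air_vapor_pressure,
    saturation_vapor_pressure,
    shortwave_from_ppfd,
)
from .photosynthesis import FarquharParams, net_assimilation
from .soil import SoilLayer, _vg_psi_k, profile_from_taw, pot_profile
from .types import GenotypeTraits, VulnerabilityCurve

MMOL_PER_MM = 1e3 / 18.0 * 1e3  # mmol water per mm water column per m2 (55555.6)

FAILURE_NOT_REACHED = math.inf  # sentinel returned when the horizon is exceeded


@dataclass
class PlantArchitecture:
    """Hydraulic architecture and micro-environmental couplings of the plant.

    Conductances in mmol m-2(leaf) s-1 MPa-1, capacitances in mol m-2 MPa-1,
    boundary-layer conductances in mmol m-2 s-1.  ``soil_layers`` must be a
    3-layer profile; ``layer_depth_mm`` are equivalent soil depths per m2 of
    leaf area (so stock = theta * depth * 55.5 mol).
    """

    soil_layers: Sequence[SoilLayer]
    layer_depth_mm: np.ndarray
    leaf_area: float = 1.0  # m2, for absolute bookkeeping only
    k_root: float = 30.0
    k_stem_leaf: float = 12.0
    k_leaf_sym: float = 25.0
    c_stem: float = 5.0
    c_leaf_apo: float = 0.25
    w_sat_leaf: float = 8.0
    v_cav_reservoir: float = 2.0
    g_bl_leaf: float = 2000.0
    g_bl_canopy: float = 1200.0
    wind_speed: float = 2.0
    absorptance_sw: float = 0.6
    emissivity: float = 0.97

    def __post_init__(self):
        self.layer_depth_mm = np.asarray(self.layer_depth_mm, dtype=float)
        if len(self.soil_layers) != self.layer_depth_mm.size:
            raise ValueError("one depth per soil layer required")
        positives = (
            self.leaf_area, self.k_root, self.k_stem_leaf, self.k_leaf_sym,
            self.c_stem, self.c_leaf_apo, self.w_sat_leaf, self.g_bl_leaf,
            self.g_bl_canopy,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("architecture conductances/capacitances must be positive")
        if self.v_cav_reservoir < 0 or self.wind_speed < 0:
            raise ValueError("v_cav_reservoir and wind_speed must be non-negative")

    #: architecture fields eligible for the extended (±fraction) screening
    PERTURBABLE = (
        "k_root", "k_stem_leaf", "k_leaf_sym", "c_stem", "c_leaf_apo",
        "w_sat_leaf", "v_cav_reservoir", "g_bl_leaf", "g_bl_canopy",
    )


@dataclass
class DiurnalForcing:
    """Square-wave day/night forcing blocks."""

    t_day: float = 25.0
    rh_day: float = 60.0
    ppfd_day: float = 1500.0
    t_night: float = 15.0
    rh_night: float = 90.0
    ppfd_night: float = 0.0
    photoperiod_h: float = 12.0
    day_start_h: float = 6.0
    co2: float = 400.0
    wind: float = 2.0

    def __post_init__(self):
        for rh in (self.rh_day, self.rh_night):
            if not (0 < rh <= 100):
                raise ValueError("RH must lie in (0, 100]")
        if self.ppfd_day < 0 or self.ppfd_night < 0:
            raise ValueError("PPFD must be non-negative")

    def at(self, t_s: float) -> tuple[float, float, float]:
        """(T_air, RH, PPFD) at clock time ``t_s`` seconds from midnight."""
        hour = (t_s / 3600.0) % 24.0
        if self.day_start_h <= hour < self.day_start_h + self.photoperiod_h:
            return self.t_day, self.rh_day, self.ppfd_day
        return self.t_night, self.rh_night, self.ppfd_night


@dataclass
class SimConfig:
    """Numerical and behavioural switches of the integrator."""

    dt: float = 60.0  # outer step, s
    dpsi_max: float = 0.2  # MPa per substep before subdivision
    max_subdivisions: int = 10
    failure_plc: float = 99.5  # "100 PLC" operationalised
    psi_floor: float = -12.0  # MPa, numerical clamp far past any failure point
    energy_balance: bool = True
    regulate_gnight: bool = True
    compute_assimilation: bool = False
    farquhar: FarquharParams = field(default_factory=FarquharParams)


# ---------------------------------------------------------------------------
# Standalone physiological relations (the spec'd operations)
# ---------------------------------------------------------------------------

def stomatal_closure_fraction(psi, pgs50, slope):
    """Sigmoid fraction of maximal stomatal opening at water potential psi."""
    psi = np.asarray(psi, dtype=float)
    return 1.0 / (1.0 + np.exp(-np.asarray(slope, float) * (psi - np.asarray(pgs50, float))))


def stomatal_conductance(
    psi_leaf,
    traits: GenotypeTraits,
    ppfd: float,
    config: SimConfig | None = None,
):
    """Stomatal conductance to vapour (mmol m-2 s-1) before boundary layers.

    Day (PPFD > 0): gc_max scaled by the closure sigmoid, floored at g_min.
    Night: g_night scaled by the same sigmoid (configurable), same floor.
    """
    cfg = config or SimConfig()
    frac = stomatal_closure_fraction(psi_leaf, traits.pgs50, traits.gs_slope)
    if ppfd > 0:
        base = traits.gc_max * frac
    else:
        base = traits.g_night * (frac if cfg.regulate_gnight else 1.0)
    return np.maximum(base, traits.g_min)


def update_plc(psi_leaf, curve: VulnerabilityCurve, plc_prev):
    """Irreversible leaf PLC: max of previous PLC and the curve at psi."""
    plc_prev = np.asarray(plc_prev, dtype=float)
    if np.any(plc_prev < 0) or np.any(plc_prev > 100):
        raise ValueError("plc_prev must lie in [0, 100]")
    return np.maximum(plc_prev, curve.pep(psi_leaf))


def series_conductance(*gs):
    """Conductances in series (harmonic combination)."""
    inv = sum(1.0 / np.maximum(np.asarray(g, dtype=float), 1e-12) for g in gs)
    return 1.0 / inv


# ---------------------------------------------------------------------------
# Vectorised engine
# ---------------------------------------------------------------------------

class Simulation:
    """Vectorised batch of soil-plant networks sharing forcing and topology.

    Trait and (optionally) architecture parameters may differ per member;
    every state variable is an ``(n,)`` array.  Scalar use is just n = 1.
    """

    TRAIT_COLS = ("gc_max", "gs_slope", "pgs50", "g_night", "g_min",
                  "pi0", "epsilon", "p50_leaf", "plc_slope")

    def __init__(
        self,
        params: pd.DataFrame,
        arch: PlantArchitecture,
        config: SimConfig | None = None,
    ):
        self.cfg = config or SimConfig()
        self.arch = arch
        self.n = len(params)
        p = {}
        for col in self.TRAIT_COLS:
            if col not in params:
                raise ValueError(f"missing trait column {col!r}")
            p[col] = np.ascontiguousarray(params[col], dtype=float)
        # architecture overrides (extended screening) fall back to scalars
        for name in PlantArchitecture.PERTURBABLE:
            p[name] = (
                np.ascontiguousarray(params[name], dtype=float)
                if name in params
                else np.full(self.n, getattr(arch, name))
            )
        # leaf-area scaling of the soil stock (lower LAI = more soil per leaf)
        lai_scale = (
            np.ascontiguousarray(params["lai_scale"], dtype=float)
            if "lai_scale" in params
            else np.ones(self.n)
        )
        self.p = p
        # derived pressure-volume quantities (capacitances in mmol m-2 MPa-1)
        pi0, eps = p["pi0"], p["epsilon"]
        self.psi_tlp = pi0 * eps / (pi0 + eps)
        x_tlp = -pi0 / eps
        self.c_ft = p["w_sat_leaf"] / (eps - pi0) * 1e3
        self.c_tlp = p["w_sat_leaf"] * (1.0 - x_tlp) ** 2 / (-pi0) * 1e3
        self.c_stem = p["c_stem"] * 1e3
        self.c_la = p["c_leaf_apo"] * 1e3
        self.v_cav = p["v_cav_reservoir"] * 1e3  # mmol m-2
        # soil layer parameter arrays (nlayer,) broadcast against (n,1)
        layers = arch.soil_layers
        self.nl = len(layers)
        self.theta_sat = np.array([l.theta_sat for l in layers])
        self.theta_res = np.array([l.theta_res for l in layers])
        self.vg_alpha = np.array([l.alpha for l in layers])
        self.vg_n = np.array([l.n_vg for l in layers])
        self.k_soil_sat = np.array([l.k_sat for l in layers])
        self.depth_mm = arch.layer_depth_mm[None, :] / lai_scale[:, None]
        self.theta_init = np.array([l.water_content for l in layers])
        # soil-to-root conductance is referenced at the initial (field
        # capacity) content: k_layer = k_sat * krel(Se)/krel(Se_init), so a
        # freshly watered profile is hydraulically non-limiting and dries
        # toward cut-off as the Mualem conductivity collapses
        _, krel0 = _vg_psi_k(
            (self.theta_init - self.theta_res) / (self.theta_sat - self.theta_res),
            self.vg_alpha, self.vg_n,
        )
        self.krel_ref = np.maximum(krel0, 1e-12)
        self.reset()

    # -- state ------------------------------------------------------------

    def reset(self, theta: Optional[np.ndarray] = None):
        n, nl = self.n, self.nl
        self.canopy_scale = 1.0  # fraction of full canopy present (phenology)
        self.theta = np.broadcast_to(
            self.theta_init if theta is None else np.asarray(theta, float), (n, nl)
        ).copy()
        psi0, _ = _vg_psi_k(
            (self.theta - self.theta_res) / (self.theta_sat - self.theta_res),
            self.vg_alpha, self.vg_n,
        )
        psi0 = psi0.mean(axis=1)
        self.psi_stem = psi0.copy()
        self.psi_la = psi0.copy()
        self.psi_ls = psi0.copy()
        self.plc = np.zeros(n)
        self.t_leaf = np.full(n, 20.0)
        self._t_leaf_set = False
        self.pending_release = np.zeros(n)
        self.cum_assim = np.zeros(n)  # mol CO2 m-2 leaf
        self.clock = 0.0
        self.failed_at = np.full(n, np.nan)
        # conservation bookkeeping (mmol m-2 leaf)
        self.transpired = np.zeros(n)
        self.soil_extracted = np.zeros(n)
        self.storage_change = np.zeros(n)
        self.cav_released = np.zeros(n)
        self.audit_max = np.zeros(n)

    @property
    def active(self) -> np.ndarray:
        return np.isnan(self.failed_at)

    # -- physics ----------------------------------------------------------

    def _soil_psi_k(self):
        se = (self.theta - self.theta_res) / (self.theta_sat - self.theta_res)
        psi, krel = _vg_psi_k(se, self.vg_alpha, self.vg_n)
        k_soil = self.k_soil_sat * krel / self.krel_ref
        k_rootpath = self.p["k_root"][:, None] * (self.k_soil_sat / self.k_soil_sat.sum())
        g = k_soil * k_rootpath / np.maximum(k_soil + k_rootpath, 1e-12)
        return psi, g

    def _surface_conductance(self, ppfd):
        """Vapour conductance gs -> canopy (mmol m-2 s-1) and its psi-derivative.

        ``ppfd`` may be a scalar or per-member array; daytime members use
        gc_max, nighttime members g_night (regulated by the same closure
        sigmoid unless configured otherwise); all floored at g_min.
        """
        p = self.p
        frac = stomatal_closure_fraction(self.psi_ls, p["pgs50"], p["gs_slope"])
        day = np.broadcast_to(np.asarray(ppfd, dtype=float) > 0, (self.n,))
        if self.cfg.regulate_gnight:
            base = np.where(day, p["gc_max"], p["g_night"])
            gs_raw = base * frac
        else:
            base = np.where(day, p["gc_max"], 0.0)
            gs_raw = np.where(day, p["gc_max"] * frac, p["g_night"])
        gs = np.maximum(gs_raw, p["g_min"])
        open_mask = gs_raw > p["g_min"]
        dgs = np.where(open_mask, base * p["gs_slope"] * frac * (1.0 - frac), 0.0)
        g_tot = series_conductance(gs, p["g_bl_leaf"], p["g_bl_canopy"])
        dgtot = (g_tot / np.maximum(gs, 1e-12)) ** 2 * dgs
        return gs, g_tot * self.canopy_scale, dgtot * self.canopy_scale

    def _substep(self, t_air, rh, ppfd, dt: float, co2: float):
        """One proposed backward-Euler substep; returns max |dpsi| proposed."""
        cfg = self.cfg
        active = self.active
        if not self._t_leaf_set:
            # before the first committed step the leaf is at air temperature
            self.t_leaf = np.broadcast_to(np.asarray(t_air, dtype=float), (self.n,)).copy()
            self._t_leaf_set = True
        e_air = np.asarray(air_vapor_pressure(t_air, rh), dtype=float)
        d_leaf = np.maximum(saturation_vapor_pressure(self.t_leaf) - e_air, 0.0)

        gs, g_tot, dgtot = self._surface_conductance(ppfd)
        e0 = g_tot * d_leaf / P_ATM  # mmol m-2 s-1
        dEdpsi = dgtot * d_leaf / P_ATM

        psi_soil, g_si = self._soil_psi_k()
        g_sum = g_si.sum(axis=1)
        k_sl = self.p["k_stem_leaf"] * np.maximum(1.0 - self.plc / 100.0, 1e-4)
        k_ls = self.p["k_leaf_sym"]
        c_ls = np.where(self.psi_ls > self.psi_tlp, self.c_ft, self.c_tlp)

        s_cav = self.pending_release / dt  # mmol m-2 s-1 into the apoplasm

        d1 = self.c_stem / dt + g_sum + k_sl
        d2 = self.c_la / dt + k_sl + k_ls
        d3 = c_ls / dt + k_ls + dEdpsi
        r1 = self.c_stem / dt * self.psi_stem + (g_si * psi_soil).sum(axis=1)
        r2 = self.c_la / dt * self.psi_la + s_cav
        r3 = c_ls / dt * self.psi_ls - e0 + dEdpsi * self.psi_ls

        d2p = d2 - k_sl * k_sl / d1
        r2p = r2 + k_sl * r1 / d1
        x3 = (r3 + k_ls * r2p / d2p) / (d3 - k_ls * k_ls / d2p)
        x2 = (r2p + k_ls * x3) / d2p
        x1 = (r1 + k_sl * x2) / d1

        dpsi_max = float(
            np.max(
                np.abs(np.stack([x1 - self.psi_stem, x2 - self.psi_la, x3 - self.psi_ls]))[
                    :, active
                ],
                initial=0.0,
            )
        )
        return (x1, x2, x3, e0, dEdpsi, g_si, psi_soil, s_cav, c_ls, gs, ppfd, t_air, co2, dt), dpsi_max

    def _commit(self, payload):
        (x1, x2, x3, e0, dEdpsi, g_si, psi_soil, s_cav, c_ls, gs, ppfd, t_air, co2, dt) = payload
        cfg = self.cfg
        active = self.active
        x1 = np.maximum(x1, cfg.psi_floor)
        x2 = np.maximum(x2, cfg.psi_floor)
        x3 = np.maximum(x3, cfg.psi_floor)

        e_used = e0 + dEdpsi * (x3 - self.psi_ls)
        flux = g_si * (psi_soil - x1[:, None])  # mmol m-2 s-1 per layer
        dstore = (
            self.c_stem * (x1 - self.psi_stem)
            + self.c_la * (x2 - self.psi_la)
            + c_ls * (x3 - self.psi_ls)
        )
        residual = (flux.sum(axis=1) + s_cav - e_used) * dt - dstore

        # explicit soil depletion from the same discrete fluxes
        stock = self.theta * self.depth_mm * MMOL_PER_MM
        stock_new = stock - np.where(active[:, None], flux, 0.0) * dt
        floor = (self.theta_res * (1.0 + 1e-9)) * self.depth_mm * MMOL_PER_MM
        clamped = np.maximum(stock_new, floor)
        residual = residual + (clamped - stock_new).sum(axis=1)
        self.theta = np.where(
            active[:, None], clamped / (self.depth_mm * MMOL_PER_MM), self.theta
        )

        self.psi_stem = np.where(active, x1, self.psi_stem)
        self.psi_la = np.where(active, x2, self.psi_la)
        self.psi_ls = np.where(active, x3, self.psi_ls)

        self.transpired += np.where(active, e_used * dt, 0.0)
        self.soil_extracted += np.where(active, flux.sum(axis=1) * dt, 0.0)
        self.storage_change += np.where(active, dstore, 0.0)
        self.cav_released += np.where(active, s_cav * dt, 0.0)
        self.audit_max = np.maximum(self.audit_max, np.where(active, np.abs(residual), 0.0))
        self.pending_release = np.where(active, 0.0, self.pending_release)

        # embolism: irreversible, evaluated on the leaf xylem potential
        pep = 100.0 / (1.0 + np.exp(self.p["plc_slope"] / 25.0 * (self.psi_la - self.p["p50_leaf"])))
        plc_prev = self.plc.copy()
        plc_new = np.maximum(self.plc, pep)
        release = self.v_cav * (plc_new - self.plc) / 100.0
        self.pending_release = np.where(active, release, self.pending_release)
        self.plc = np.where(active, plc_new, self.plc)

        # leaf temperature (linearised energy balance, semi-implicit in E)
        t_air = np.broadcast_to(np.asarray(t_air, dtype=float), (self.n,))
        if cfg.energy_balance:
            sw = np.asarray(shortwave_from_ppfd(ppfd), dtype=float)
            rn = self.arch.absorptance_sw * sw
            le = LAMBDA_MOL * np.maximum(e_used, 0.0) * 1e-3
            g_bh = self.p["g_bl_leaf"] * 1e-3
            t_k = t_air + 273.15
            denom = CP_MOL * g_bh + 4.0 * self.arch.emissivity * SIGMA_SB * t_k**3
            t_new = t_air + (rn - le) / denom
        else:
            t_new = t_air
        self.t_leaf = np.where(active, t_new, self.t_leaf)

        if cfg.compute_assimilation:
            a = net_assimilation(ppfd, self.t_leaf, gs, co2, cfg.farquhar)
            self.cum_assim += np.where(active, a * dt * 1e-6 * self.canopy_scale, 0.0)

        newly_failed = active & (self.plc >= cfg.failure_plc)
        if np.any(newly_failed):
            # linear interpolation of the threshold crossing within the substep
            dplc = np.maximum(self.plc - plc_prev, 1e-12)
            frac_t = np.clip((cfg.failure_plc - plc_prev) / dplc, 0.0, 1.0)
            self.failed_at = np.where(
                newly_failed, self.clock + frac_t * dt, self.failed_at
            )

    def advance(self, t_air, rh, ppfd, dt: float, co2: float = 400.0):
        """Advance every member by ``dt`` seconds under constant forcing
        (scalars or per-member arrays), subdividing adaptively until
        per-substep potential changes are small."""
        n_sub = 1
        for _ in range(self.cfg.max_subdivisions):
            payload, dpsi = self._substep(t_air, rh, ppfd, dt / n_sub, co2)
            if dpsi <= self.cfg.dpsi_max or n_sub >= 2**self.cfg.max_subdivisions:
                break
            n_sub *= 2
        sub_dt = dt / n_sub
        for i in range(n_sub):
            if i > 0:
                payload, _ = self._substep(t_air, rh, ppfd, sub_dt, co2)
            self._commit(payload)
            self.clock += sub_dt
        return self

    # -- drivers ----------------------------------------------------------

    def run(
        self,
        forcing: DiurnalForcing,
        days: float,
        dt: Optional[float] = None,
        record_every: Optional[float] = None,
        stop_when_all_failed: bool = True,
    ) -> Optional[pd.DataFrame]:
        """Run under square-wave diurnal forcing for ``days`` days.

        Returns a tidy record DataFrame when ``record_every`` (seconds) is
        given, else None.  Stops early once every member has failed.
        """
        dt = dt or self.cfg.dt
        steps = int(round(days * 86400.0 / dt))
        records = []
        next_record = 0.0
        for _ in range(steps):
            t_air, rh, ppfd = forcing.at(self.clock)
            if record_every is not None and self.clock >= next_record:
                records.append(self.snapshot())
                next_record += record_every
            self.advance(t_air, rh, ppfd, dt, forcing.co2)
            if stop_when_all_failed and not np.any(self.active):
                break
        if record_every is not None:
            if self.clock >= next_record:
                records.append(self.snapshot())
            return pd.concat(records, ignore_index=True)
        return None

    def snapshot(self) -> pd.DataFrame:
        gs, g_tot, _ = self._surface_conductance(ppfd=1.0)  # daytime view of gs
        d = {
            "clock_s": self.clock,
            "member": np.arange(self.n),
            "psi_stem": self.psi_stem,
            "psi_leaf_apo": self.psi_la,
            "psi_leaf_sym": self.psi_ls,
            "plc_leaf": self.plc,
            "t_leaf": self.t_leaf,
            "gs": gs,
            "cum_assim": self.cum_assim,
            "transpired_mmol": self.transpired,
        }
        for i in range(self.nl):
            d[f"theta_{i + 1}"] = self.theta[:, i]
        return pd.DataFrame(d)

    def days_to_failure(self) -> np.ndarray:
        """Continuous failure times in days (inf where not reached)."""
        out = self.failed_at / 86400.0
        return np.where(np.isnan(out), FAILURE_NOT_REACHED, out)

    def conservation_residual(self) -> np.ndarray:
        """Closure of the water budget, relative to total transpiration."""
        closure = self.soil_extracted + self.cav_released - self.transpired - self.storage_change
        return np.abs(closure) / np.maximum(self.transpired, 1e-9)


# ---------------------------------------------------------------------------
# Scenario builders and convenience drivers
# ---------------------------------------------------------------------------

def load_default_parameters() -> dict:
    """The packaged default parameter file (architecture, soil, forcing,
    numerics) as a nested dict; every value is overridable through the
    corresponding constructor."""
    import yaml
    from importlib import resources

    with resources.as_file(
        resources.files("ideovine.data") / "default_simulation.yaml"
    ) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def vineyard_architecture(
    taw_mm: float = 180.0,
    lai: float = 1.5,
    texture: dict | None = None,
    **overrides,
) -> PlantArchitecture:
    """Field architecture: ``taw_mm`` of available soil water under a canopy
    of leaf area index ``lai`` (soil depth is re-expressed per m2 leaf)."""
    layers, depths = profile_from_taw(taw_mm=taw_mm, texture=texture)
    return PlantArchitecture(soil_layers=layers, layer_depth_mm=depths / lai, **overrides)


def pot_architecture(
    water_capacity_l: float = 2.8,
    leaf_area: float = 0.30,
    **overrides,
) -> PlantArchitecture:
    """Greenhouse mini-lysimeter pot: small soil store, short hydraulic path."""
    layers, depths = pot_profile(water_capacity_l=water_capacity_l, leaf_area=leaf_area)
    overrides.setdefault("k_root", 60.0)
    overrides.setdefault("k_stem_leaf", 40.0)
    overrides.setdefault("k_leaf_sym", 80.0)
    overrides.setdefault("g_bl_leaf", 1e5)
    overrides.setdefault("g_bl_canopy", 1e5)
    return PlantArchitecture(
        soil_layers=layers, layer_depth_mm=depths, leaf_area=leaf_area, **overrides
    )


def standard_forcing() -> DiurnalForcing:
    """The reference dry-down forcing: 25 degC / 60% RH / 1500 PPFD by day,
    15 degC / 90% RH / dark by night."""
    return DiurnalForcing()


def traits_frame(traits: GenotypeTraits | Sequence[GenotypeTraits]) -> pd.DataFrame:
    if isinstance(traits, GenotypeTraits):
        traits = [traits]
    return pd.DataFrame([{c: getattr(t, c) for c in Simulation.TRAIT_COLS} for t in traits])


def step(
    state: Simulation,
    forcing: DiurnalForcing,
    dt: float,
) -> Simulation:
    """Single-step driver kept for symmetry with the operation contract."""
    t_air, rh, ppfd = forcing.at(state.clock)
    return state.advance(t_air, rh, ppfd, dt, forcing.co2)


def simulate_to_failure(
    traits,
    arch: Optional[PlantArchitecture] = None,
    forcing: Optional[DiurnalForcing] = None,
    dt: float = 600.0,
    horizon_days: float = 400.0,
    config: Optional[SimConfig] = None,
) -> np.ndarray | float:
    """Days to leaf hydraulic failure under a no-rain dry-down from field
    capacity.  Accepts one GenotypeTraits, a sequence, or a parameter
    DataFrame; returns a float for single input, else an array.  Members
    that never reach the failure threshold get ``math.inf``.
    """
    single = isinstance(traits, GenotypeTraits)
    params = traits_frame(traits) if (single or isinstance(traits, (list, tuple))) else traits
    arch = arch or vineyard_architecture()
    forcing = forcing or standard_forcing()
    sim = Simulation(params, arch, config)
    sim.run(forcing, days=horizon_days, dt=dt, record_every=None)
    days = sim.days_to_failure()
    return float(days[0]) if single else days
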