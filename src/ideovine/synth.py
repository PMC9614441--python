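"""Seeded generators for every input class, with embedded ground truth.

Each generator forward-simulates the measurement protocol it emulates
(mini-lysimeter dry-down, bench-dry pressure-volume curve, detached-leaf
mass loss, optical scan sequence, daily weather series) from known
parameters, so that every analysis stage can be tested by round-trip
recovery without external data.  Noise models are deliberately simple:
Gaussian balance noise and salt-and-pepper scan noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import meteo
from .simulator import (
    DiurnalForcing,
    PlantArchitecture,
    SimConfig,
    Simulation,
    pot_architecture,
    traits_frame,
)
from .types import GenotypeTraits, LysimeterSeries, OpticalStack, PVSeries


@dataclass
class GroundTruth:
    """Parameters, noise settings and seed behind a generated dataset."""

    params: dict
    noise: dict
    seed: int


# ---------------------------------------------------------------------------
# Mini-lysimeter dry-down
# ---------------------------------------------------------------------------

@dataclass
class DrydownDataset:
    series: LysimeterSeries
    truth: GroundTruth
    record: pd.DataFrame  # simulator state at sampling times (diagnostics)


def greenhouse_forcing() -> DiurnalForcing:
    """Greenhouse-like blocks: warm bright day at saturating light, mild night."""
    return DiurnalForcing(
        t_day=24.0, rh_day=55.0, ppfd_day=1000.0,
        t_night=18.0, rh_night=80.0, photoperiod_h=13.0,
    )


def gen_drydown_dataset(
    truth: GenotypeTraits,
    days: float = 30.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    sample_every_s: float = 1200.0,
    psi_pd_every_days: int = 2,
    pot_water_l: float = 3.5,
    tare_g: float = 9000.0,
    arch: Optional[PlantArchitecture] = None,
    forcing: Optional[DiurnalForcing] = None,
) -> DrydownDataset:
    """Weighed-pot dry-down of a plant with traits ``truth``.

    The pot plant is modelled as tightly coupled to its soil (large plant
    conductances, negligible boundary layers, leaf at air temperature), the
    regime under which a stomatal fit against predawn water potential is
    unbiased.  Weight carries Gaussian balance noise of ``noise_sd`` g;
    predawn water potential is sampled every ``psi_pd_every_days`` days
    before dawn, as in the pressure-chamber protocol.
    """
    if days < 5:
        raise ValueError("a dry-down needs at least 5 days")
    rng = np.random.default_rng(seed)
    forcing = forcing or greenhouse_forcing()
    arch = arch or pot_architecture(
        water_capacity_l=pot_water_l,
        leaf_area=truth.leaf_area,
        k_root=1500.0, k_stem_leaf=1500.0, k_leaf_sym=1500.0,
    )
    cfg = SimConfig(energy_balance=False)
    sim = Simulation(traits_frame(truth), arch, cfg)

    dt = 300.0
    n_steps = int(round(days * 86400.0 / dt))
    sample_every = max(1, int(round(sample_every_s / dt)))
    predawn_hour = forcing.day_start_h - 0.5

    times, weights, t_air_l, rh_l, ppfd_l = [], [], [], [], []
    psi_t, psi_v = [], []
    snapshots = []
    for i in range(n_steps):
        t_air, rh, ppfd = forcing.at(sim.clock)
        hour = (sim.clock / 3600.0) % 24.0
        day_idx = int(sim.clock // 86400.0)
        if i % sample_every == 0:
            soil_mm = float((sim.theta * sim.depth_mm).sum())  # mm per m2 leaf
            water_g = soil_mm * truth.leaf_area * 1e3  # 1 mm m-2 leaf = 1 L m-2
            times.append(sim.clock)
            weights.append(tare_g + water_g)
            t_air_l.append(t_air)
            rh_l.append(rh)
            ppfd_l.append(ppfd)
            snapshots.append(
                (sim.clock, float(sim.psi_ls[0]), float(sim.plc[0]), float(sim.transpired[0]))
            )
        if (
            day_idx % psi_pd_every_days == 0
            and abs(hour - predawn_hour) < dt / 7200.0
            and (not psi_t or sim.clock - psi_t[-1] > 43200.0)
        ):
            psi_t.append(sim.clock)
            psi_v.append(float(sim.psi_ls[0]))
        sim.advance(t_air, rh, ppfd, dt, forcing.co2)

    weights = np.asarray(weights) + rng.normal(0.0, noise_sd, size=len(weights))
    series = LysimeterSeries(
        time=np.asarray(times),
        weight=np.maximum(weights, 0.0),
        air_temp=np.asarray(t_air_l),
        rh=np.asarray(rh_l),
        ppfd=np.asarray(ppfd_l),
        psi_pd_time=np.asarray(psi_t),
        psi_pd=np.asarray(psi_v),
    )
    record = pd.DataFrame(snapshots, columns=["clock_s", "psi_leaf", "plc", "transpired_mmol"])
    gt = GroundTruth(
        params=truth.to_dict(),
        noise={"balance_sd_g": noise_sd},
        seed=seed,
    )
    return DrydownDataset(series=series, truth=gt, record=record)


# ---------------------------------------------------------------------------
# Pressure-volume curve and detached-leaf mass loss
# ---------------------------------------------------------------------------

@dataclass
class PVMassLossDataset:
    pv: PVSeries
    mass_time_s: np.ndarray
    mass_g: np.ndarray
    vpd_kpa: float
    leaf_area_m2: float
    truth: GroundTruth


def gen_pv_and_massloss(
    pi0: float,
    epsilon: float,
    g_min: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 16,
    turgid_weight: float = 2.0,
    dry_weight: float = 0.4,
    leaf_area_m2: float = 0.004,
    chamber_t: float = 25.0,
    chamber_rh: float = 45.0,
    e_initial_factor: float = 4.0,
    stomatal_tau_s: float = 900.0,
    duration_h: float = 6.0,
) -> PVMassLossDataset:
    """Pressure-volume pairs plus a mass-loss trace from known parameters.

    The PV relations are the standard ones: turgor P = -pi0 - eps*x and
    osmotic potential pi = pi0/(1 - x) with x the symplasm water deficit.
    The mass-loss trace has an initial stomatal phase decaying with time
    constant ``stomatal_tau_s`` onto the constant cuticular rate
    E_min = g_min * D / P.
    """
    if not (pi0 < 0 < epsilon):
        raise ValueError("need pi0 < 0 and epsilon > 0")
    rng = np.random.default_rng(seed)
    x_tlp = -pi0 / epsilon
    x = np.linspace(0.02, min(2.4 * x_tlp, 0.6), n_points)
    turgor = np.maximum(-pi0 - epsilon * x, 0.0)
    osmotic = pi0 / (1.0 - x)
    psi = turgor + osmotic
    mass = dry_weight + (turgid_weight - dry_weight) * (1.0 - x)
    if noise_sd > 0:
        mass = mass + rng.normal(0.0, noise_sd, size=mass.size)
    pv = PVSeries(psi_leaf=psi, mass=mass, turgid_weight=turgid_weight, dry_weight=dry_weight)

    d = float(meteo.vpd(chamber_t, chamber_rh))
    e_min = g_min * d / meteo.P_ATM  # mmol m-2 s-1
    e0 = e_initial_factor * max(e_min, 0.05)
    t_dense = np.arange(0, duration_h * 3600.0, 60.0)
    e_t = (e0 - e_min) * np.exp(-t_dense / stomatal_tau_s) + e_min
    loss_g = np.cumsum(e_t) * 60.0 * 1e-3 * meteo.MW_WATER * leaf_area_m2
    m0 = 1.8
    sample_t = np.concatenate(
        [np.arange(0, 3600.0, 600.0), np.arange(3600.0, duration_h * 3600.0, 900.0)]
    )
    mass_s = m0 - np.interp(sample_t, t_dense, loss_g)
    if noise_sd > 0:
        mass_s = mass_s + rng.normal(0.0, noise_sd * 2e-4, size=mass_s.size)
    gt = GroundTruth(
        params={"pi0": pi0, "epsilon": epsilon, "g_min": g_min,
                "psi_tlp": pi0 * epsilon / (pi0 + epsilon), "vpd": d},
        noise={"pv_mass_sd_g": noise_sd},
        seed=seed,
    )
    return PVMassLossDataset(
        pv=pv, mass_time_s=sample_t, mass_g=mass_s, vpd_kpa=d,
        leaf_area_m2=leaf_area_m2, truth=gt,
    )


# ---------------------------------------------------------------------------
# Optical scan stack
# ---------------------------------------------------------------------------

@dataclass
class OpticalDataset:
    stack: OpticalStack
    truth: GroundTruth
    scheduled_area: np.ndarray  # embolised pixels introduced per frame


def gen_optical_stack(
    curve,
    frames: int = 120,
    seed: int = 0,
    shape: tuple[int, int] = (160, 160),
    budget_px: int = 4000,
    noise_density: float = 0.0,
    frame_interval_s: float = 300.0,
    psi_start: float = -0.1,
) -> OpticalDataset:
    """Scan sequence of a dehydrating leaf with scheduled embolism events.

    Stem water potential declines linearly over the sequence; the number of
    pixels toggled at each frame follows the increments of the vulnerability
    curve so that cumulative embolised area tracks PEP(psi) exactly.  Events
    are 3x3 pixel blocks (surviving a 3x3 median filter); optional
    salt-and-pepper noise flips isolated pixels per frame.
    """
    if frames < 10:
        raise ValueError("need at least 10 frames")
    rng = np.random.default_rng(seed)
    h, w = shape
    t = np.arange(frames) * frame_interval_s
    psi_end = curve.psi_at(99.8) - 0.2
    psi = np.linspace(psi_start, psi_end, frames)

    frac = curve.pep(psi) / curve.pep(psi[-1])  # normalised cumulative fraction
    target_px = np.round(frac * budget_px).astype(int)
    new_px = np.diff(target_px, prepend=target_px[0])
    new_px[0] = 0  # the first frame has no predecessor to difference against

    # non-overlapping 3x3 blocks drawn from a shuffled grid
    bh, bw = h // 3, w // 3
    blocks = np.arange(bh * bw)
    rng.shuffle(blocks)
    base = np.full(shape, 120, dtype=np.uint8)
    img = base.copy()
    frames_out = []
    used = 0
    scheduled = np.zeros(frames)
    for i in range(frames):
        n_blocks = int(round(new_px[i] / 9.0))
        for b in blocks[used : used + n_blocks]:
            r, c = divmod(int(b), bw)
            img[3 * r : 3 * r + 3, 3 * c : 3 * c + 3] = 210
        scheduled[i] = n_blocks * 9
        used += n_blocks
        frame = img.copy()
        if noise_density > 0:
            mask = rng.random(shape) < noise_density
            frame[mask] = rng.choice([0, 255], size=int(mask.sum())).astype(np.uint8)
        frames_out.append(frame)

    psi_times = np.arange(-1.0, t[-1] + 1801.0, 1800.0)
    psi_vals = np.interp(psi_times, t, psi)
    stack = OpticalStack(
        frames=frames_out, frame_times=t, psi_times=psi_times, psi_values=psi_vals
    )
    gt = GroundTruth(
        params={"p50": curve.p50, "slope": curve.slope, "budget_px": budget_px},
        noise={"salt_pepper_density": noise_density},
        seed=seed,
    )
    return OpticalDataset(stack=stack, truth=gt, scheduled_area=scheduled)


# ---------------------------------------------------------------------------
# Daily weather
# ---------------------------------------------------------------------------

def gen_weather(
    years: int = 1,
    seed: int = 0,
    start_year: int = 2030,
    t_annual_mean: float = 13.5,
    t_seasonal_amp: float = 9.0,
    t_diurnal_range: float = 10.0,
    rh_mean: float = 70.0,
    rh_summer_drop: float = 15.0,
    rain_freq_winter: float = 0.35,
    rain_freq_summer: float = 0.10,
    rain_mean_mm: float = 7.0,
    radiation_peak: float = 26.0,
    wind: float = 2.0,
    warming_per_decade: float = 0.0,
    rain_change_per_decade: float = 0.0,
) -> pd.DataFrame:
    """Synthetic temperate daily weather with optional climate trends.

    Seasonality is sinusoidal (warm dry summers); rain days are Bernoulli
    draws with exponential amounts.  ``warming_per_decade`` (degC) and
    ``rain_change_per_decade`` (fractional, e.g. -0.05) impose linear
    trends emulating end-of-century trajectories.  Deterministic per seed.
    """
    if years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    year_offset = (dates.year - start_year).to_numpy(float)
    n = len(dates)
    season = np.sin(2.0 * np.pi * (doy - 110) / 365.0)  # peaks mid-summer
    t_mean = t_annual_mean + t_seasonal_amp * season + warming_per_decade * year_offset / 10.0
    rh = np.clip(rh_mean - rh_summer_drop * np.maximum(season, 0.0), 20.0, 98.0)
    rad = np.maximum(radiation_peak * (0.45 + 0.55 * season), 2.0)
    p_rain = rain_freq_winter + (rain_freq_summer - rain_freq_winter) * np.maximum(season, 0.0)
    rain_scale = np.maximum(1.0 + rain_change_per_decade * year_offset / 10.0, 0.0)
    wet = rng.random(n) < p_rain
    amounts = rng.exponential(1.0, size=n) * rain_mean_mm * rain_scale
    df = pd.DataFrame(
        {
            "date": dates,
            "t_min": t_mean - t_diurnal_range / 2.0,
            "t_max": t_mean + t_diurnal_range / 2.0,
            "rh_mean": rh,
            "radiation": rad,
            "rain": np.where(wet, amounts, 0.0),
            "wind": float(wind),
        }
    )
    df.attrs["ground_truth"] = GroundTruth(
        params={
            "t_annual_mean": t_annual_mean,
            "warming_per_decade": warming_per_decade,
            "rain_mean_mm": rain_mean_mm,
            "rain_change_per_decade": rain_change_per_decade,
        },
        noise={},
        seed=seed,
    ).__dict__
    return df
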