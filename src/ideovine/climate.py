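"""Multi-year seasonal projection: daily weather in, per-year maximum leaf
PLC, failure days and cumulative assimilation out.

Each year is independent: on DOY 1 the soil is reset to field capacity and
leaf PLC to zero.  Canopy leaf area follows the phenology calendar (linear
ramp from budbreak to full canopy, linear senescent decline, bare after
defoliation).  Rain infiltrates the top layer to field capacity, cascades
to deeper layers, and any surplus runs off; direct soil evaporation is
neglected.  Daily weather is disaggregated to hourly forcing (cosine air
temperature between Tmin and Tmax, constant absolute humidity, half-sine
PPFD integrating to the daily radiation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import meteo
from .simulator import (
    MMOL_PER_MM,
    PlantArchitecture,
    SimConfig,
    Simulation,
    traits_frame,
)
from .soil import profile_from_taw
from .types import GenotypeTraits, PhenologyCalendar

WEATHER_COLUMNS = ("date", "t_min", "t_max", "rh_mean", "radiation", "rain", "wind")


def load_daily_weather(path_or_df) -> pd.DataFrame:
    """Read and validate a daily weather series.

    Expects columns date (ISO-8601), t_min/t_max (degC), rh_mean (%),
    radiation (MJ m-2 d-1), rain (mm), wind (m s-1).  Dates must be unique
    and contiguous (daily); violations raise with a report.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather file lacks columns: {missing}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    dup = df["date"].duplicated()
    if dup.any():
        raise ValueError(f"duplicated dates: {list(df.loc[dup, 'date'].dt.date)[:5]}")
    gaps = df["date"].diff().dropna()
    bad = gaps[gaps != pd.Timedelta(days=1)]
    if not bad.empty:
        raise ValueError(f"non-contiguous dates around {df.loc[bad.index, 'date'].dt.date.tolist()[:5]}")
    if (df["t_min"] > df["t_max"]).any():
        raise ValueError("t_min exceeds t_max on some days")
    if (df["rain"] < 0).any():
        raise ValueError("negative rainfall")
    return df


def subdaily_forcing(
    t_min: float,
    t_max: float,
    rh_mean: float,
    radiation_mj: float,
    hours: np.ndarray,
    daylength_h: float = 14.0,
    t_min_hour: float = 5.0,
    t_max_hour: float = 15.0,
):
    """Hourly (T, RH, PPFD) from daily values.

    Air temperature follows a cosine between ``t_min`` (at ``t_min_hour``)
    and ``t_max`` (at ``t_max_hour``); absolute humidity is held at the
    value implied by ``rh_mean`` at the daily mean temperature (RH capped
    at 99%); PPFD is a half-sine centred on solar noon whose integral
    matches the daily radiation.
    """
    hours = np.asarray(hours, dtype=float)
    t_mean = 0.5 * (t_min + t_max)
    amp = 0.5 * (t_max - t_min)
    # piecewise cosine hitting the minimum at t_min_hour and the maximum at
    # t_max_hour exactly (the two half-periods differ in length)
    rising = (hours >= t_min_hour) & (hours <= t_max_hour)
    t_air = np.where(
        rising,
        t_mean - amp * np.cos(np.pi * (hours - t_min_hour) / (t_max_hour - t_min_hour)),
        t_mean + amp * np.cos(
            np.pi * ((hours - t_max_hour) % 24.0) / (24.0 - (t_max_hour - t_min_hour))
        ),
    )
    e_air = float(meteo.air_vapor_pressure(t_mean, rh_mean))
    rh = np.clip(e_air / meteo.saturation_vapor_pressure(t_air) * 100.0, 1.0, 99.0)
    noon = 12.0
    half = daylength_h / 2.0
    in_day = np.abs(hours - noon) < half
    peak = float(meteo.ppfd_from_daily_radiation(radiation_mj, daylength_h))
    ppfd = np.where(in_day, peak * np.sin(np.pi * (hours - (noon - half)) / daylength_h), 0.0)
    return t_air, rh, np.maximum(ppfd, 0.0)


@dataclass
class ProjectionConfig:
    dt: float = 1200.0  # integration step within each hour block, s
    hours_per_day: int = 24
    failure_plc: float = 99.5
    co2: float = 400.0
    interception_fraction: float = 0.0  # canopy rain interception
    lai_floor: float = 0.02  # numerical floor on canopy scaling
    compute_assimilation: bool = True


def run_multiyear_projection(
    traits: GenotypeTraits | pd.DataFrame,
    weather: pd.DataFrame,
    calendar: PhenologyCalendar | None = None,
    arch: Optional[PlantArchitecture] = None,
    config: ProjectionConfig | None = None,
    sim_config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Season-by-season hydraulic projection over a multi-year weather series.

    All complete years are simulated in one vectorised batch (years are
    independent by construction: fresh soil and zero PLC on DOY 1).
    Returns one row per year: max_leaf_plc, failure_doy (NaN when the
    threshold is never crossed), total_assimilation (mol CO2 m-2 ground)
    and the seasonal rain total.  Partial years are skipped with a warning.
    """
    import warnings

    cal = calendar or PhenologyCalendar()
    cfg = config or ProjectionConfig()
    weather = load_daily_weather(weather)
    weather = weather.assign(year=weather["date"].dt.year, doy=weather["date"].dt.dayofyear)
    years = []
    blocks = []
    for year, grp in weather.groupby("year"):
        if len(grp) < 365:
            warnings.warn(f"skipping partial year {year} ({len(grp)} days)")
            continue
        years.append(int(year))
        blocks.append(grp.iloc[:365])
    if not years:
        raise ValueError("weather series contains no complete year")
    ny = len(years)

    if arch is None:
        layers, depths = profile_from_taw(taw_mm=cal.taw_mm)
        arch = PlantArchitecture(soil_layers=layers, layer_depth_mm=depths / cal.lai_max)
    scfg = sim_config or SimConfig(
        failure_plc=cfg.failure_plc, compute_assimilation=cfg.compute_assimilation
    )
    scfg.compute_assimilation = cfg.compute_assimilation

    params = traits_frame(traits) if isinstance(traits, GenotypeTraits) else traits
    if len(params) != 1:
        raise ValueError("one trait set per projection run")
    batch = pd.concat([params] * ny, ignore_index=True)
    sim = Simulation(batch, arch, scfg)

    theta_fc = sim.theta_init.copy()

    tmin = np.stack([b["t_min"].to_numpy(float) for b in blocks])  # (ny, 365)
    tmax = np.stack([b["t_max"].to_numpy(float) for b in blocks])
    rhm = np.stack([b["rh_mean"].to_numpy(float) for b in blocks])
    rad = np.stack([b["radiation"].to_numpy(float) for b in blocks])
    rain = np.stack([b["rain"].to_numpy(float) for b in blocks])

    max_plc = np.zeros(ny)
    failure_doy = np.full(ny, np.nan)
    hours = np.arange(cfg.hours_per_day, dtype=float) + 0.5
    steps_per_hour = max(1, int(round(3600.0 / cfg.dt)))
    dt = 3600.0 / steps_per_hour

    for d in range(365):
        doy = d + 1
        lai_frac = max(float(cal.lai(doy)) / cal.lai_max, cfg.lai_floor)
        # canopy vapour coupling scales with the foliage present
        sim.canopy_scale = lai_frac
        rain_basis_mm = rain[:, d] * (1.0 - cfg.interception_fraction) / cal.lai_max
        if np.any(rain_basis_mm > 0):
            _infiltrate(sim, rain_basis_mm, theta_fc)
        # hourly forcing per year (vectorised across years within the hour)
        t_air, rh, ppfd = _day_forcing(tmin[:, d], tmax[:, d], rhm[:, d], rad[:, d], hours)
        for h in range(cfg.hours_per_day):
            for _ in range(steps_per_hour):
                sim.advance(t_air[:, h], rh[:, h], ppfd[:, h], dt, cfg.co2)
        max_plc = np.maximum(max_plc, sim.plc)
        crossed = np.isnan(failure_doy) & (sim.plc >= cfg.failure_plc)
        failure_doy[crossed] = doy

    out = pd.DataFrame(
        {
            "year": years,
            "max_leaf_plc": np.minimum(max_plc, 100.0),
            "failure_doy": failure_doy,
            "total_assimilation": sim.cum_assim * cal.lai_max,  # per m2 ground
            "rain_total_mm": rain.sum(axis=1),
        }
    )
    return out


def _day_forcing(tmin, tmax, rhm, rad, hours):
    ny = tmin.size
    t_air = np.empty((ny, hours.size))
    rh = np.empty_like(t_air)
    ppfd = np.empty_like(t_air)
    for i in range(ny):
        t_air[i], rh[i], ppfd[i] = subdaily_forcing(tmin[i], tmax[i], rhm[i], rad[i], hours)
    return t_air, rh, ppfd


def _infiltrate(sim: Simulation, rain_basis_mm: np.ndarray, theta_fc: np.ndarray):
    """Top-down cascade: fill each layer to field capacity, excess runs off.

    ``rain_basis_mm`` is rain already converted to the simulation's
    per-leaf-area basis (mm of water per basis m2)."""
    surplus = rain_basis_mm.astype(float).copy()
    for i in range(sim.nl):
        capacity_mm = np.maximum((theta_fc[i] - sim.theta[:, i]) * sim.depth_mm[:, i], 0.0)
        take = np.clip(surplus, 0.0, capacity_mm)
        sim.theta[:, i] = sim.theta[:, i] + take / sim.depth_mm[:, i]
        surplus = np.maximum(surplus - take, 0.0)
    # remaining surplus leaves the rhizosphere (runoff / deep drainage)


def decade_summary(seasons: pd.DataFrame) -> pd.DataFrame:
    """Decade bins: mean maximum seasonal PLC and count of failure years."""
    df = seasons.copy()
    df["decade"] = (df["year"] // 10) * 10
    return (
        df.groupby("decade")
        .agg(
            mean_max_plc=("max_leaf_plc", "mean"),
            failure_years=("failure_doy", lambda s: int(s.notna().sum())),
            n_years=("year", "count"),
        )
        .reset_index()
    )
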