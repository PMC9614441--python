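"""Psychrometric helpers shared by trait derivation and the hydraulic simulator.

All temperatures are in degrees Celsius, pressures in kPa, conductances in
mmol m-2 s-1 and water fluxes in mmol m-2 s-1 unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

R_GAS = 8.314462618  # J mol-1 K-1
MW_WATER = 18.0  # g mol-1 (the conventional round value used in Eq. handling)
MW_AIR = 28.965  # g mol-1
P_ATM = 101.325  # kPa, standard atmosphere
LAMBDA_MOL = 44.0e3  # J mol-1, latent heat of vaporisation of water
CP_MOL = 29.2  # J mol-1 K-1, molar heat capacity of air
SIGMA_SB = 5.670374419e-8  # W m-2 K-4

#: Slope of the conductance coefficient K_G with absolute temperature,
#: kPa m3 kg-1 K-1.  The ideal-gas form K_G = (R / M_w) * T_K is exactly
#: linear in T, so the "linear approximation" carries no error; both
#: coefficients remain overridable for users who prefer published empirical
#: linearisations.
KG_SLOPE = R_GAS / MW_WATER * 1e3 / 1e3  # == R/M_w in kPa m3 kg-1 K-1 (0.46152)
KG_INTERCEPT = KG_SLOPE * 273.15

#: Photosynthetically active radiation: J (PAR) -> umol photons.
PAR_J_TO_UMOL = 4.57
#: Fraction of broadband shortwave that is PAR.
SW_PAR_FRACTION = 0.45


def saturation_vapor_pressure(t_c):
    """Saturation vapour pressure (kPa) from the Tetens formula."""
    t_c = np.asarray(t_c, dtype=float)
    return 0.61078 * np.exp(17.27 * t_c / (t_c + 237.3))


def air_vapor_pressure(t_c, rh):
    """Actual vapour pressure (kPa) of air at ``t_c`` degC and ``rh`` % RH."""
    return saturation_vapor_pressure(t_c) * np.asarray(rh, dtype=float) / 100.0


def vpd(t_c, rh):
    """Air vapour-pressure deficit D (kPa).

    Raises ``ValueError`` for RH outside (0, 100]: RH = 0 leaves D undefined
    relative to any leaf-air coupling assumption and such samples must be
    rejected upstream.
    """
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in (0, 100] %")
    return saturation_vapor_pressure(t_c) * (1.0 - rh / 100.0)


def kg_coefficient(t_c, intercept: float = KG_INTERCEPT, slope: float = KG_SLOPE):
    """Conductance coefficient K_G(T) in kPa m3 kg-1.

    K_G converts a mass transpiration flux (kg m-2 s-1) divided by the
    vapour-pressure deficit (kPa) into a canopy conductance in m s-1.  The
    default coefficients are the ideal-gas values (K_G = R T_K / M_w), which
    keep the mass-unit and molar-unit conductance routes mutually consistent.
    """
    return intercept + slope * np.asarray(t_c, dtype=float)


def molar_density_air(t_c, p_kpa: float = P_ATM):
    """Molar density of air (mol m-3) from the ideal gas law."""
    return np.asarray(p_kpa, dtype=float) * 1e3 / (R_GAS * (np.asarray(t_c, dtype=float) + 273.15))


def conductance_from_flux(
    e_mmol,
    t_c,
    rh,
    p_kpa: float = P_ATM,
    kg_intercept: float = KG_INTERCEPT,
    kg_slope: float = KG_SLOPE,
):
    """Canopy conductance Gc (mmol m-2 s-1) from transpiration and VPD.

    Implements the K_G(T) simplification: Gc[m s-1] = K_G(T) * E[kg] / D,
    then converts to molar units with the molar density of air.
    """
    d = vpd(t_c, rh)
    e_kg = np.asarray(e_mmol, dtype=float) * MW_WATER * 1e-6  # mmol -> kg m-2 s-1
    gc_ms = kg_coefficient(t_c, kg_intercept, kg_slope) * e_kg / d
    return gc_ms * molar_density_air(t_c, p_kpa) * 1e3  # m s-1 -> mmol m-2 s-1


def flux_from_conductance(
    gc_mmol,
    t_c,
    rh,
    p_kpa: float = P_ATM,
    kg_intercept: float = KG_INTERCEPT,
    kg_slope: float = KG_SLOPE,
):
    """Inverse of :func:`conductance_from_flux`: transpiration in mmol m-2 s-1."""
    d = vpd(t_c, rh)
    gc_ms = np.asarray(gc_mmol, dtype=float) / 1e3 / molar_density_air(t_c, p_kpa)
    e_kg = gc_ms * d / kg_coefficient(t_c, kg_intercept, kg_slope)
    return e_kg / (MW_WATER * 1e-6)


def shortwave_from_ppfd(ppfd):
    """Broadband shortwave irradiance (W m-2) implied by a PPFD (umol m-2 s-1)."""
    return np.asarray(ppfd, dtype=float) / PAR_J_TO_UMOL / SW_PAR_FRACTION


def ppfd_from_daily_radiation(radiation_mj, daylength_h):
    """Peak PPFD (umol m-2 s-1) of a half-sine diurnal course integrating to
    ``radiation_mj`` MJ m-2 d-1 of broadband shortwave."""
    radiation_mj = np.asarray(radiation_mj, dtype=float)
    par_umol = radiation_mj * 1e6 * SW_PAR_FRACTION * PAR_J_TO_UMOL
    # integral of peak*sin(pi*x) over daylength seconds = peak * 2/pi * L
    seconds = np.asarray(daylength_h, dtype=float) * 3600.0
    return par_umol * np.pi / (2.0 * seconds)
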