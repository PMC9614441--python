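"""Farquhar-type net CO2 assimilation coupled to stomatal supply.

The biochemical demand (minimum of Rubisco- and RuBP-regeneration-limited
rates, with Arrhenius temperature responses of Vcmax, Jmax, Kc, Ko and
Gamma*) is solved jointly with the CO2 supply through stomata,
A = g_c (Ca - Ci), in closed form (quadratic per limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_GAS = 8.314462618


@dataclass
class FarquharParams:
    """Biochemical parameters at 25 degC (grapevine-typical defaults)."""

    vcmax25: float = 60.0  # umol m-2 s-1
    jmax25: float = 120.0  # umol m-2 s-1
    rd25: float = 1.0  # umol m-2 s-1
    kc25: float = 404.9  # umol mol-1
    ko25: float = 278.4  # mmol mol-1
    gamma_star25: float = 42.75  # umol mol-1
    ea_vcmax: float = 65330.0  # J mol-1
    ea_jmax: float = 43540.0
    ea_rd: float = 46390.0
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    ea_gamma: float = 37830.0
    alpha_q: float = 0.3  # e- per photon, effective quantum yield
    theta_j: float = 0.9  # curvature of the light response
    o2: float = 210.0  # mmol mol-1


def _arrhenius(k25, ea, t_c):
    tk = np.asarray(t_c, dtype=float) + 273.15
    return k25 * np.exp(ea * (tk - 298.15) / (298.15 * R_GAS * tk))


def electron_transport(ppfd, jmax, alpha_q=0.3, theta=0.9):
    """Non-rectangular-hyperbola electron transport rate J."""
    i2 = np.asarray(ppfd, dtype=float) * alpha_q
    b = i2 + jmax
    return (b - np.sqrt(np.maximum(b * b - 4.0 * theta * i2 * jmax, 0.0))) / (2.0 * theta)


def _colimited(x1, x2, gc, ca, gamma_star, rd):
    """Positive-supply solution of A = x1 (Ci - Gamma*)/(Ci + x2) - Rd with
    Ci = Ca - A/gc.  Quadratic closed form; returns the physical root."""
    a = -1.0 / gc
    b = (ca + x2) + (x1 - rd) / gc
    c = rd * (ca + x2) - x1 * (ca - gamma_star)
    disc = np.sqrt(np.maximum(b * b - 4.0 * a * c, 0.0))
    # a < 0: the smaller-magnitude (physical) root is (-b + disc)/(2a)
    return (-b + disc) / (2.0 * a)


def net_assimilation(ppfd, t_leaf, gs_mmol, co2=400.0, params: FarquharParams | None = None):
    """Net assimilation A (umol m-2 s-1) for stomatal conductance ``gs_mmol``
    (to water vapour, mmol m-2 s-1), leaf temperature and ambient CO2 (ppm).

    Dark (PPFD = 0) returns the respiration-only rate -Rd(T).
    """
    p = params or FarquharParams()
    gs_mmol = np.asarray(gs_mmol, dtype=float)
    if np.any(gs_mmol < 0):
        raise ValueError("gs must be non-negative")
    gc = np.maximum(gs_mmol / 1.6 / 1e3, 1e-9)  # mol CO2 m-2 s-1
    vcmax = _arrhenius(p.vcmax25, p.ea_vcmax, t_leaf)
    jmax = _arrhenius(p.jmax25, p.ea_jmax, t_leaf)
    rd = _arrhenius(p.rd25, p.ea_rd, t_leaf)
    kc = _arrhenius(p.kc25, p.ea_kc, t_leaf)
    ko = _arrhenius(p.ko25, p.ea_ko, t_leaf)
    gamma = _arrhenius(p.gamma_star25, p.ea_gamma, t_leaf)
    km = kc * (1.0 + p.o2 / ko)
    j = electron_transport(ppfd, jmax, p.alpha_q, p.theta_j)
    ac = _colimited(vcmax, km, gc, co2, gamma, rd)
    aj = _colimited(j / 4.0, 2.0 * gamma, gc, co2, gamma, rd)
    a = np.minimum(ac, aj)
    # fully closed stomata exchange nothing: respiration only
    return np.where(gs_mmol <= 1e-6, -rd, a)
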