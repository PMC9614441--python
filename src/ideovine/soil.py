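"""Van Genuchten-Mualem soil water retention and conductance.

Pedo-transfer closed forms mapping volumetric water content to soil water
potential (MPa) and relative hydraulic conductance.  ``alpha`` is expressed
in MPa-1 so potentials come out directly in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: lower clamp on effective saturation to keep the closed forms finite
_SE_MIN = 1e-9
#: floor on soil water potential (MPa); beyond this the layer is hydraulically inert
PSI_SOIL_FLOOR = -100.0


@dataclass
class SoilLayer:
    """One layer of the rootable soil profile.

    theta_sat/theta_res: m3 m-3; alpha: MPa-1; n_vg > 1; k_sat in
    mmol m-2(leaf) s-1 MPa-1 at saturation for the soil-to-root pathway of
    this layer; water_content: current theta (m3 m-3); thickness_fraction:
    share of the rootable profile.
    """

    theta_sat: float
    theta_res: float
    alpha: float
    n_vg: float
    k_sat: float
    water_content: float
    thickness_fraction: float

    def __post_init__(self):
        if not self.n_vg > 1:
            raise ValueError("n_vg must exceed 1")
        if not (0 <= self.theta_res < self.theta_sat):
            raise ValueError("need 0 <= theta_res < theta_sat")
        if not (self.theta_res < self.water_content <= self.theta_sat):
            raise ValueError("water_content must lie in (theta_res, theta_sat]")
        if self.alpha <= 0 or self.k_sat < 0 or not (0 < self.thickness_fraction <= 1):
            raise ValueError("invalid soil layer parameters")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg

    def theta_at(self, psi_mpa: float) -> float:
        """Water content at matric potential ``psi_mpa`` (<= 0)."""
        h = -float(psi_mpa)
        if h <= 0:
            return self.theta_sat
        se = (1.0 + (self.alpha * h) ** self.n_vg) ** (-self.m_vg)
        return self.theta_res + se * (self.theta_sat - self.theta_res)


def effective_saturation(theta, layer: SoilLayer):
    theta = np.asarray(theta, dtype=float)
    se = (theta - layer.theta_res) / (layer.theta_sat - layer.theta_res)
    return np.clip(se, _SE_MIN, 1.0)


def soil_water_retention(layer: SoilLayer, theta=None):
    """Water potential (MPa) and conductance of a layer at content ``theta``.

    Returns ``(psi_soil, k_soil)`` with psi_soil <= 0 and k_soil =
    k_sat * Mualem relative conductivity.  Raises for contents at or below
    residual (the plant cannot extract there).
    """
    theta = layer.water_content if theta is None else theta
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= layer.theta_res):
        raise ValueError("water content at or below residual: no extractable water")
    se = effective_saturation(theta_arr, layer)
    psi, krel = _vg_psi_k(se, layer.alpha, layer.n_vg)
    out_psi = psi if np.ndim(theta) else float(psi)
    k = layer.k_sat * krel
    return out_psi, (k if np.ndim(theta) else float(k))


def _vg_psi_k(se, alpha, n):
    """Vectorised Van Genuchten psi (MPa) and Mualem relative conductivity."""
    se = np.clip(np.asarray(se, dtype=float), _SE_MIN, 1.0)
    alpha = np.asarray(alpha, dtype=float)
    n = np.asarray(n, dtype=float)
    m = 1.0 - 1.0 / n
    with np.errstate(over="ignore"):
        psi = -(1.0 / alpha) * np.maximum(se ** (-1.0 / m) - 1.0, 0.0) ** (1.0 / n)
    psi = np.maximum(psi, PSI_SOIL_FLOOR)
    krel = np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    return psi, krel


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

#: default loam-like texture for the vineyard scenario
DEFAULT_TEXTURE = dict(theta_sat=0.43, theta_res=0.06, alpha=300.0, n_vg=2.1)
#: matric potentials bounding the total available water (field capacity / wilting)
PSI_FIELD_CAPACITY = -0.033
PSI_WILTING = -1.5


def profile_from_taw(
    taw_mm: float = 180.0,
    fractions: Sequence[float] = (0.3, 0.3, 0.4),
    texture: dict | None = None,
    k_sat_total: float = 5e4,
    psi_fc: float = PSI_FIELD_CAPACITY,
    psi_wilt: float = PSI_WILTING,
) -> tuple[list[SoilLayer], np.ndarray]:
    """Build a 3-layer profile holding ``taw_mm`` mm of available water.

    The TAW (water held between ``psi_fc`` and ``psi_wilt``) is distributed
    across layers by ``fractions``; each layer's equivalent depth (mm of
    soil) follows from the texture's available-water fraction.  Returns the
    layers (initialised at field capacity) and their depths in mm.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("layer fractions must sum to 1")
    tex = dict(DEFAULT_TEXTURE)
    if texture:
        tex.update(texture)
    probe = SoilLayer(
        **tex, k_sat=1.0, water_content=tex["theta_sat"], thickness_fraction=1.0
    )
    theta_fc = probe.theta_at(psi_fc)
    theta_wilt = probe.theta_at(psi_wilt)
    awc = theta_fc - theta_wilt  # m3 water per m3 soil between the bounds
    depths_mm = taw_mm * fractions / awc
    layers = [
        SoilLayer(
            **tex,
            k_sat=k_sat_total * f,
            water_content=theta_fc,
            thickness_fraction=f,
        )
        for f in fractions
    ]
    return layers, depths_mm


#: peat-like potting substrate: wide, gradual water release across tension,
#: as for a horticultural mix; keeps the pot hydraulically well-coupled
POT_TEXTURE = dict(theta_sat=0.50, theta_res=0.08, alpha=50.0, n_vg=1.15)


def pot_profile(
    water_capacity_l: float = 3.5,
    leaf_area: float = 0.30,
    texture: dict | None = None,
    k_sat_total: float = 1e5,
) -> tuple[list[SoilLayer], np.ndarray]:
    """Single-texture 3-layer profile for a greenhouse pot.

    ``water_capacity_l`` is the plant-available water of the pot (litres);
    depths are expressed as mm per m2 of leaf area so that the simulator's
    leaf-area basis holds exactly that volume.
    """
    taw_mm = water_capacity_l / leaf_area  # 1 L per m2 == 1 mm
    return profile_from_taw(
        taw_mm=taw_mm,
        fractions=(0.34, 0.33, 0.33),
        texture=texture or dict(POT_TEXTURE),
        k_sat_total=k_sat_total,
    )
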