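"""Domain containers for hydraulic phenotyping and simulation.

The containers are thin validated dataclasses; heavy tabular data stays in
pandas DataFrames / numpy arrays held by these objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Optional, Sequence

import numpy as np

LN9 = math.log(9.0)


# ---------------------------------------------------------------------------
# Raw measurement series
# ---------------------------------------------------------------------------

@dataclass
class LysimeterSeries:
    """Continuously-weighed pot record with concurrent greenhouse climate.

    time: seconds since start (strictly increasing); weight: g; air_temp: degC;
    rh: % in (0, 100]; ppfd: umol m-2 s-1; psi_pd: optional sparse predawn
    water-potential observations (time_s, MPa).
    """

    time: np.ndarray
    weight: np.ndarray
    air_temp: np.ndarray
    rh: np.ndarray
    ppfd: np.ndarray
    psi_pd_time: Optional[np.ndarray] = None
    psi_pd: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("time", "weight", "air_temp", "rh", "ppfd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        for name in ("weight", "air_temp", "rh", "ppfd"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must have the same length as time")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.weight < 0):
            raise ValueError("weight must be non-negative")
        if np.any(self.rh <= 0) or np.any(self.rh > 100):
            raise ValueError("rh must lie in (0, 100]")
        if (self.psi_pd is None) != (self.psi_pd_time is None):
            raise ValueError("psi_pd and psi_pd_time must be supplied together")
        if self.psi_pd is not None:
            self.psi_pd = np.asarray(self.psi_pd, dtype=float)
            self.psi_pd_time = np.asarray(self.psi_pd_time, dtype=float)


@dataclass
class PVSeries:
    """Bench-dry pressure-volume record for one leaf.

    psi_leaf in MPa (negative, decreasing along the series), masses in g.
    """

    psi_leaf: np.ndarray
    mass: np.ndarray
    turgid_weight: float
    dry_weight: float

    def __post_init__(self):
        self.psi_leaf = np.asarray(self.psi_leaf, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.psi_leaf.size != self.mass.size:
            raise ValueError("psi_leaf and mass must have the same length")
        if not (0 < self.dry_weight < self.turgid_weight):
            raise ValueError("need 0 < dry_weight < turgid_weight")
        if np.any(self.mass <= 0):
            raise ValueError("all masses must be positive")
        if np.any(np.diff(self.psi_leaf) >= 0):
            raise ValueError("psi_leaf must be strictly decreasing (drying leaf)")

    @property
    def rwc(self) -> np.ndarray:
        """Relative water content, % of turgid."""
        return (self.mass - self.dry_weight) / (self.turgid_weight - self.dry_weight) * 100.0


@dataclass
class VulnerabilityCurve:
    """Sigmoid vulnerability curve: percentage embolism as a function of Psi.

    ``p50`` is the water potential (MPa, negative) at 50% embolism and
    ``slope`` (% MPa-1, positive) the slope at the inflexion point.
    """

    p50: float
    slope: float

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError("slope must be positive")
        if not self.p50 < 0:
            raise ValueError("p50 must be negative")

    def pep(self, psi):
        """Percent embolism at water potential ``psi`` (MPa)."""
        psi = np.asarray(psi, dtype=float)
        return 100.0 / (1.0 + np.exp(self.slope / 25.0 * (psi - self.p50)))

    @property
    def p12(self) -> float:
        return 50.0 / self.slope + self.p50

    @property
    def p88(self) -> float:
        return -50.0 / self.slope + self.p50

    def psi_at(self, pep_percent: float) -> float:
        """Water potential at which the curve reaches ``pep_percent`` embolism."""
        if not 0 < pep_percent < 100:
            raise ValueError("pep_percent must lie strictly between 0 and 100")
        return self.p50 + 25.0 / self.slope * math.log(100.0 / pep_percent - 1.0)


@dataclass
class OpticalStack:
    """Ordered grayscale frames of a dehydrating leaf plus a stem-Psi trace."""

    frames: Sequence[np.ndarray]
    frame_times: np.ndarray
    psi_times: np.ndarray
    psi_values: np.ndarray

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.psi_times = np.asarray(self.psi_times, dtype=float)
        self.psi_values = np.asarray(self.psi_values, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("need at least two frames")
        shape = np.asarray(self.frames[0]).shape
        for f in self.frames:
            if np.asarray(f).shape != shape:
                raise ValueError("all frames must share one shape")
        if self.frame_times.size != len(self.frames):
            raise ValueError("frame_times must match number of frames")
        if self.psi_times[0] > self.frame_times[0] or self.psi_times[-1] < self.frame_times[-1]:
            raise ValueError("psi trace must span the frame interval")

    def psi_at_frames(self) -> np.ndarray:
        return np.interp(self.frame_times, self.psi_times, self.psi_values)


# ---------------------------------------------------------------------------
# Derived traits
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTraits:
    """The hydraulic trait set of one genotype.

    Units: conductances mmol m-2 s-1; potentials MPa (negative); slopes
    MPa-1 (stomata) and % MPa-1 (embolism); capacitances mol m-2 MPa-1;
    leaf_area m2.
    """

    name: str
    gc_max: float
    e_max: float
    pgs50: float
    gs_slope: float
    psi_gs90: float
    g_night: float
    g_min: float
    pi0: float
    epsilon: float
    psi_tlp: float
    c_ft: float
    c_tlp: float
    p50_leaf: float
    p12_leaf: float
    p88_leaf: float
    plc_slope: float
    hsm_p12: float
    hsm_p50: float
    leaf_area: float = 1.0

    _TOL = 1e-6

    def __post_init__(self):
        if not (self.p88_leaf <= self.p50_leaf <= self.p12_leaf < 0):
            raise ValueError("need p88 <= p50 <= p12 < 0")
        if not (self.psi_tlp <= self.pi0 < 0):
            raise ValueError("need psi_tlp <= pi0 < 0")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if abs(self.hsm_p50 - (self.psi_gs90 - self.p50_leaf)) > self._TOL:
            raise ValueError("hsm_p50 must equal psi_gs90 - p50_leaf")
        if abs(self.hsm_p12 - (self.psi_gs90 - self.p12_leaf)) > self._TOL:
            raise ValueError("hsm_p12 must equal psi_gs90 - p12_leaf")
        for name in ("gc_max", "e_max", "g_night", "g_min", "c_ft", "c_tlp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.g_min <= self.g_night <= self.gc_max):
            raise ValueError("need g_min <= g_night <= gc_max")
        if self.leaf_area <= 0:
            raise ValueError("leaf_area must be positive")

    @classmethod
    def from_measured(
        cls,
        name: str,
        gc_max: float,
        pgs50: float,
        gs_slope: float,
        g_night: float,
        g_min: float,
        pi0: float,
        epsilon: float,
        p50_leaf: float,
        plc_slope: float,
        leaf_area: float = 1.0,
        e_max: Optional[float] = None,
        w_sat: float = 8.0,
        vpd_ref: float = 1.27,
        p_atm: float = 101.325,
    ) -> "GenotypeTraits":
        """Build the full trait record from the eight measured parameters.

        Derived fields use the closed forms: psi_gs90 = pgs50 - ln(9)/slp,
        psi_tlp = pi0*eps/(pi0+eps), P12/P88 = +-50/slp + P50, HSM_Px =
        psi_gs90 - Px.  Symplasm capacitances come from the standard
        pressure-volume relations with a saturated leaf water content
        ``w_sat`` (mol m-2).  ``e_max`` defaults to the Fickian flux of a
        fully open canopy at the reference VPD ``vpd_ref``.
        """
        psi_gs90 = pgs50 - LN9 / gs_slope
        psi_tlp = pi0 * epsilon / (pi0 + epsilon)
        x_tlp = -pi0 / epsilon
        c_ft = w_sat / (epsilon - pi0)
        c_tlp = w_sat * (1.0 - x_tlp) ** 2 / (-pi0)
        curve = VulnerabilityCurve(p50=p50_leaf, slope=plc_slope)
        if e_max is None:
            e_max = gc_max * vpd_ref / p_atm
        return cls(
            name=name,
            gc_max=gc_max,
            e_max=e_max,
            pgs50=pgs50,
            gs_slope=gs_slope,
            psi_gs90=psi_gs90,
            g_night=g_night,
            g_min=g_min,
            pi0=pi0,
            epsilon=epsilon,
            psi_tlp=psi_tlp,
            c_ft=c_ft,
            c_tlp=c_tlp,
            p50_leaf=p50_leaf,
            p12_leaf=curve.p12,
            p88_leaf=curve.p88,
            plc_slope=plc_slope,
            hsm_p12=psi_gs90 - curve.p12,
            hsm_p50=psi_gs90 - p50_leaf,
            leaf_area=leaf_area,
        )

    @property
    def vulnerability_curve(self) -> VulnerabilityCurve:
        return VulnerabilityCurve(p50=self.p50_leaf, slope=self.plc_slope)

    def closure_fraction(self, psi):
        """Fraction of maximal stomatal opening at water potential ``psi``."""
        psi = np.asarray(psi, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.gs_slope * (psi - self.pgs50)))

    def to_dict(self) -> dict:
        return asdict(self)

    #: the eight parameters screened in the ideotype library
    MEASURED_FIELDS = (
        "gc_max",
        "pgs50",
        "g_night",
        "g_min",
        "pi0",
        "epsilon",
        "p50_leaf",
        "plc_slope",
    )


def trait_field_names() -> list[str]:
    return [f.name for f in fields(GenotypeTraits) if f.name != "name"]


# ---------------------------------------------------------------------------
# Weather and phenology
# ---------------------------------------------------------------------------

@dataclass
class PhenologyCalendar:
    """Seasonal canopy calendar of a vineyard (day-of-year thresholds)."""

    budbreak_doy: int = 120
    full_canopy_doy: int = 140
    senescence_start_doy: int = 200
    defoliation_doy: int = 290
    lai_max: float = 1.5
    taw_mm: float = 180.0

    def __post_init__(self):
        seq = (self.budbreak_doy, self.full_canopy_doy, self.senescence_start_doy, self.defoliation_doy)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("phenology DOYs must be strictly increasing")

    def lai(self, doy):
        """Leaf area index at ``doy``: linear ramp to full canopy, linear
        senescent decline after ``senescence_start_doy``, zero after
        defoliation."""
        doy = np.asarray(doy, dtype=float)
        up = np.clip((doy - self.budbreak_doy) / (self.full_canopy_doy - self.budbreak_doy), 0.0, 1.0)
        down = np.clip(
            (self.defoliation_doy - doy) / (self.defoliation_doy - self.senescence_start_doy), 0.0, 1.0
        )
        return self.lai_max * np.minimum(up, down)


@dataclass
class SeasonResult:
    """Outcome of one simulated growing season."""

    year: int
    max_leaf_plc: float
    failure_doy: Optional[int]
    total_assimilation: float  # mol CO2 m-2 ground

    def __post_init__(self):
        if not (0.0 <= self.max_leaf_plc <= 100.0):
            raise ValueError("max_leaf_plc must lie in [0, 100]")
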