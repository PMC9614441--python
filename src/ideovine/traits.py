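"""Derivation of hydraulic traits from raw phenotyping data streams.

Covers the lysimeter balance analysis (transpiration and canopy
conductance), the stomatal-closure sigmoid, pressure-volume curve analysis,
minimum conductance from detached-leaf mass loss, the leaf-area allometry
and the assembly of the per-genotype trait summary.  Optical vulnerability
imaging lives in :mod:`ideovine.optical`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import meteo
from .types import GenotypeTraits, LysimeterSeries, PVSeries, VulnerabilityCurve

LN9 = math.log(9.0)


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails; carries the residual diagnostics."""

    def __init__(self, message: str, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# Balance data analysis
# ---------------------------------------------------------------------------

def transpiration_and_conductance(
    series: LysimeterSeries,
    leaf_area: float,
    window_s: float = 1800.0,
    light_min: float = 800.0,
    kg_intercept: float = meteo.KG_INTERCEPT,
    kg_slope: float = meteo.KG_SLOPE,
) -> pd.DataFrame:
    """Transpiration E and canopy conductance Gc from a weighed-pot record.

    E = (-dW/dt) / A_L / MW_w with the weight rate estimated by a centred
    difference over ``window_s`` seconds (balance-noise suppression);
    Gc = K_G(T) * E / D.  Gc is retained only at saturating light
    (PPFD > ``light_min``); elsewhere it is NaN.

    Returns a DataFrame with columns time, e (mmol m-2 s-1), gc (mmol
    m-2 s-1), vpd (kPa), light_ok.
    """
    if leaf_area <= 0:
        raise ValueError("leaf_area must be positive")
    t, w = series.time, series.weight
    half = window_s / 2.0
    w_lo = np.interp(t - half, t, w)
    w_hi = np.interp(t + half, t, w)
    t_lo = np.maximum(t - half, t[0])
    t_hi = np.minimum(t + half, t[-1])
    slope = (w_hi - w_lo) / np.maximum(t_hi - t_lo, 1e-9)  # g s-1
    e = -slope / leaf_area / meteo.MW_WATER * 1e3  # mmol m-2 s-1

    d = meteo.vpd(series.air_temp, series.rh)
    gc = meteo.conductance_from_flux(
        e, series.air_temp, series.rh, kg_intercept=kg_intercept, kg_slope=kg_slope
    )
    light_ok = series.ppfd > light_min
    gc = np.where(light_ok, gc, np.nan)
    return pd.DataFrame(
        {"time": t, "e": e, "gc": gc, "vpd": d, "light_ok": light_ok}
    )


def gc_psi_pairs(
    series: LysimeterSeries,
    balance: pd.DataFrame,
    hour_range: tuple[float, float] = (9.0, 17.0),
    pairing: str = "weight",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair light-filtered Gc samples with a concurrent water potential.

    ``pairing='weight'`` maps the sparse predawn potentials onto pot weight
    (both reflect the same soil water store, so the predawn-Psi-vs-weight
    relation transfers predawn readings to any sampling time without the
    bias of interpolating in time while the pot dries within the day);
    ``pairing='time'`` is plain temporal interpolation.  ``hour_range``
    keeps midday samples whose differencing window does not straddle the
    dawn/dusk light transitions.
    """
    if series.psi_pd is None:
        raise ValueError("series carries no predawn water potentials")
    hours = (series.time / 3600.0) % 24.0
    keep = (hours >= hour_range[0]) & (hours <= hour_range[1])
    gc = np.where(keep, balance["gc"].to_numpy(), np.nan)
    if pairing == "weight":
        w_at_pd = np.interp(series.psi_pd_time, series.time, series.weight)
        order = np.argsort(w_at_pd)
        psi = np.interp(series.weight, w_at_pd[order], series.psi_pd[order])
    elif pairing == "time":
        psi = np.interp(series.time, series.psi_pd_time, series.psi_pd)
    else:
        raise ValueError("pairing must be 'weight' or 'time'")
    return gc, psi


@dataclass
class GcResponseFit:
    """Fitted stomatal-closure sigmoid Gc(Psi) = gsm / (1 + exp(-slp (Psi - Pgs50)))."""

    gsm: float
    slp: float
    pgs50: float
    psi_gs90: float
    residuals: np.ndarray
    psi_kind: str = "predawn"

    def predict(self, psi):
        return gc_sigmoid(np.asarray(psi, dtype=float), self.gsm, self.slp, self.pgs50)


def gc_sigmoid(psi, gsm, slp, pgs50):
    """Stomatal closure sigmoid; Gc -> gsm as Psi -> 0- for slp > 0."""
    return gsm / (1.0 + np.exp(-slp * (psi - pgs50)))


def fit_gc_response(
    gc: np.ndarray,
    psi: np.ndarray,
    psi_kind: str = "predawn",
    p0: Optional[Sequence[float]] = None,
) -> GcResponseFit:
    """Least-squares fit of canopy conductance against leaf water potential.

    ``psi_kind`` records whether the driver was predawn or midday leaf water
    potential (both occur in practice; the fit is agnostic).  The 90%-closure
    threshold follows in closed form: psi_gs90 = Pgs50 - ln(9)/slp.
    """
    gc = np.asarray(gc, dtype=float)
    psi = np.asarray(psi, dtype=float)
    ok = np.isfinite(gc) & np.isfinite(psi)
    gc, psi = gc[ok], psi[ok]
    if gc.size < 6:
        raise ValueError("need at least 6 paired (psi, Gc) points")
    if p0 is None:
        gsm0 = float(np.nanmax(gc))
        half = gc <= 0.5 * gsm0
        pgs0 = float(psi[half].max()) if half.any() else float(np.median(psi))
        p0 = (gsm0, 5.0, pgs0)
    try:
        popt, _ = optimize.curve_fit(
            gc_sigmoid,
            psi,
            gc,
            p0=p0,
            bounds=([1e-9, 1e-3, -20.0], [1e5, 200.0, 0.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        res = gc - gc_sigmoid(psi, *p0)
        raise FitError(f"stomatal sigmoid fit did not converge: {err}", res) from err
    gsm, slp, pgs50 = map(float, popt)
    if gsm <= 0:
        raise FitError("fitted gsm is non-positive", gc - gc_sigmoid(psi, *popt))
    return GcResponseFit(
        gsm=gsm,
        slp=slp,
        pgs50=pgs50,
        psi_gs90=pgs50 - LN9 / slp,
        residuals=gc - gc_sigmoid(psi, *popt),
        psi_kind=psi_kind,
    )


# ---------------------------------------------------------------------------
# Pressure-volume curves
# ---------------------------------------------------------------------------

@dataclass
class PVAnalysis:
    psi_tlp: float
    pi0: float
    epsilon: float
    c_ft: float  # RWC fraction per MPa (x w_sat gives mol m-2 MPa-1)
    c_tlp: float
    rwc_tlp: float
    breakpoint_index: int


def analyze_pv_curve(pv: PVSeries, min_post_tlp: int = 5) -> PVAnalysis:
    """Turgor-loss-point analysis of a bench-dry pressure-volume curve.

    The inverse water potential -1/Psi is plotted against water deficit
    (100 - RWC).  The transition between the nonlinear (turgid) and linear
    (post-turgor-loss) regions is found by exhaustive breakpoint search
    minimising the residual sum of squares of the post-TLP line (ties broken
    toward more post-TLP points).  The osmotic potential at full turgor is
    pi0 = -1/intercept of that line at RWC = 100; turgor pressure over the
    turgid region (Psi minus the osmotic line) regressed on water deficit
    gives the modulus of elasticity and, at its zero crossing, the TLP.
    """
    rwc = pv.rwc
    x = (100.0 - rwc) / 100.0  # water deficit, fraction
    psi = pv.psi_leaf
    usable = psi < -1e-9  # a fully hydrated leaf (Psi = 0) has divergent -1/Psi
    x, psi, rwc = x[usable], psi[usable], rwc[usable]
    n = x.size
    if n < min_post_tlp + 2:
        raise ValueError("too few valid points for a pressure-volume analysis")
    y = -1.0 / psi

    best = None
    # ascending j: among (near-)tied RSS the earliest breakpoint wins, i.e.
    # the split with more post-TLP points
    for j in range(2, n - min_post_tlp + 1):
        a, b = np.polyfit(x[j:], y[j:], 1)
        rss = float(np.sum((y[j:] - (a * x[j:] + b)) ** 2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, j, a, b)
    if best is None:
        raise ValueError(f"fewer than {min_post_tlp} points beyond zero turgor")
    _, j, a, b = best
    if b <= 0:
        raise ValueError("degenerate osmotic line (non-positive intercept)")
    pi0 = -1.0 / b

    # turgor pressure on the pre-TLP region against the extrapolated osmotic line
    pre = slice(0, max(j, 2))
    osmotic = -1.0 / (a * x[pre] + b)
    turgor = psi[pre] - osmotic
    if np.count_nonzero(turgor > 0) < 2:
        raise ValueError("no positive-turgor region found before the breakpoint")
    c1, c0 = np.polyfit(x[pre], turgor, 1)
    if c1 >= 0:
        raise ValueError("turgor must decline with water deficit")
    epsilon = -c1  # MPa per unit RWC fraction
    x_tlp = -c0 / c1
    psi_tlp = -1.0 / (a * x_tlp + b)
    if not psi_tlp < pi0:
        # fall back to the breakpoint sample when the regression root is degenerate
        psi_tlp = float(-1.0 / (a * x[j] + b))
        x_tlp = float(x[j])

    # capacitances: RWC change per MPa near full turgor and past the TLP
    c_ft = _capacitance(x[pre], psi[pre])
    c_tlp = _capacitance(x[j:], psi[j:])
    return PVAnalysis(
        psi_tlp=float(psi_tlp),
        pi0=float(pi0),
        epsilon=float(epsilon),
        c_ft=c_ft,
        c_tlp=c_tlp,
        rwc_tlp=float(100.0 * (1.0 - x_tlp)),
        breakpoint_index=int(j),
    )


def _capacitance(x, psi) -> float:
    slope, _ = np.polyfit(psi, 1.0 - x, 1)[:2]
    return float(abs(slope))


# ---------------------------------------------------------------------------
# Minimum conductance
# ---------------------------------------------------------------------------

@dataclass
class GminResult:
    g_min: float  # mmol m-2 s-1
    e_steady: float  # mmol m-2 s-1
    start_index: int
    r_squared: float


def estimate_gmin(
    time_s: np.ndarray,
    mass_g: np.ndarray,
    vpd_kpa: float,
    leaf_area_m2: float,
    patm_kpa: float = meteo.P_ATM,
    r2_min: float = 0.99,
    min_points: int = 5,
    area_basis: str = "projected",
) -> GminResult:
    """Minimum (cuticular) conductance from a detached-leaf mass-loss record.

    The steady state is the longest terminal window whose mass-time
    regression is linear (R^2 >= ``r2_min``); its slope gives E and
    g_min = E * P / D.  ``area_basis`` fixes the lamina-area convention:
    'projected' (one-sided, default) or 'total' (both sides, area doubled).
    """
    t = np.asarray(time_s, dtype=float)
    m = np.asarray(mass_g, dtype=float)
    if t.size != m.size or t.size < min_points:
        raise ValueError("need matched time/mass arrays with enough points")
    if vpd_kpa <= 0 or leaf_area_m2 <= 0:
        raise ValueError("vpd and leaf area must be positive")
    area = leaf_area_m2 * (2.0 if area_basis == "total" else 1.0)

    candidates = []
    for i in range(0, t.size - min_points + 1):
        res = stats.linregress(t[i:], m[i:])
        ss_tot = float(np.sum((m[i:] - m[i:].mean()) ** 2))
        r2 = 1.0 if ss_tot < 1e-24 else res.rvalue**2
        candidates.append((i, res.slope, r2))
        if r2 >= r2_min:
            e = -res.slope / area / meteo.MW_WATER * 1e3  # mmol m-2 s-1
            e = max(e, 0.0)
            return GminResult(
                g_min=e * patm_kpa / vpd_kpa,
                e_steady=e,
                start_index=i,
                r_squared=r2,
            )
    summary = ", ".join(f"[{i}:] R2={r2:.4f}" for i, _, r2 in candidates[:10])
    raise ValueError(f"no steady-state segment found; candidate windows: {summary}")


# ---------------------------------------------------------------------------
# Leaf vulnerability curve (fit of the optical PEP series)
# ---------------------------------------------------------------------------

def pep_sigmoid(psi, p50, slp):
    return 100.0 / (1.0 + np.exp(slp / 25.0 * (np.asarray(psi, float) - p50)))


def fit_vulnerability_curve(
    pep: np.ndarray, psi_stem: np.ndarray
) -> tuple[VulnerabilityCurve, float, float]:
    """Fit PEP(Psi) = 100 / (1 + exp(slp/25 (Psi - P50))).

    Returns the curve plus (P12, P88) from the closed forms
    P12 = 50/slp + P50 and P88 = -50/slp + P50.
    """
    pep = np.asarray(pep, dtype=float)
    psi = np.asarray(psi_stem, dtype=float)
    ok = np.isfinite(pep) & np.isfinite(psi)
    pep, psi = pep[ok], psi[ok]
    if pep.size < 6:
        raise ValueError("need at least 6 (psi, PEP) points spanning the rise")
    if np.any(pep < -1e-9) or np.any(pep > 100 + 1e-9):
        raise ValueError("PEP must lie in [0, 100]")
    if np.ptp(pep) < 1.0:
        raise ValueError("degenerate flat PEP series: no embolism rise to fit")
    p50_0 = float(np.interp(50.0, pep[np.argsort(pep)], psi[np.argsort(pep)]))
    try:
        popt, _ = optimize.curve_fit(
            pep_sigmoid,
            psi,
            pep,
            p0=(min(p50_0, -1e-3), 50.0),
            bounds=([-30.0, 1e-2], [-1e-6, 5000.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise FitError(f"vulnerability fit did not converge: {err}") from err
    curve = VulnerabilityCurve(p50=float(popt[0]), slope=float(popt[1]))
    return curve, curve.p12, curve.p88


# ---------------------------------------------------------------------------
# Leaf area allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometricModel:
    """Leaf area from midrib length: power law or through-origin linear."""

    kind: str  # 'power' or 'linear'
    a: float
    b: float  # exponent (power) or 0 (linear)
    cv_rmse_power: float
    cv_rmse_linear: float

    def predict(self, length):
        length = np.asarray(length, dtype=float)
        if np.any(length < 0):
            raise ValueError("lengths must be non-negative")
        if self.kind == "power":
            return self.a * length**self.b
        return self.a * length


def leaf_area_allometry(midrib_lengths, areas) -> AllometricModel:
    """Calibrate the midrib-length -> leaf-area relation.

    Fits a power law a*L^b (log-log least squares) and a through-origin
    linear model; the form with lower leave-one-out cross-validated RMSE
    wins (recorded on the model).  Both force zero area at zero length.
    """
    length = np.asarray(midrib_lengths, dtype=float)
    area = np.asarray(areas, dtype=float)
    if length.size < 10:
        raise ValueError("need at least 10 calibration pairs")
    if np.any(length <= 0) or np.any(area <= 0):
        raise ValueError("calibration lengths and areas must be positive")

    def loo(predict_fn_builder):
        errs = np.empty(length.size)
        for i in range(length.size):
            mask = np.ones(length.size, dtype=bool)
            mask[i] = False
            fn = predict_fn_builder(length[mask], area[mask])
            errs[i] = fn(length[i]) - area[i]
        return float(np.sqrt(np.mean(errs**2)))

    def power_builder(ln, ar):
        b, loga = np.polyfit(np.log(ln), np.log(ar), 1)
        return lambda x: math.exp(loga) * x**b

    def linear_builder(ln, ar):
        a = float(np.sum(ln * ar) / np.sum(ln * ln))
        return lambda x: a * x

    cv_power = loo(power_builder)
    cv_linear = loo(linear_builder)
    b, loga = np.polyfit(np.log(length), np.log(area), 1)
    a_lin = float(np.sum(length * area) / np.sum(length * length))
    if cv_power <= cv_linear:
        return AllometricModel("power", math.exp(loga), float(b), cv_power, cv_linear)
    return AllometricModel("linear", a_lin, 0.0, cv_power, cv_linear)


# ---------------------------------------------------------------------------
# Genotype summary
# ---------------------------------------------------------------------------

def derive_genotype_summary(
    name: str,
    gc_fit: GcResponseFit,
    pv: PVAnalysis,
    curve: VulnerabilityCurve,
    g_min: float,
    g_night: float,
    leaf_area: float,
    e_series: Optional[pd.DataFrame] = None,
    psi_pd: Optional[np.ndarray] = None,
    e_plateau_psi: float = -0.3,
    w_sat: float = 8.0,
) -> GenotypeTraits:
    """Assemble the GenotypeTraits record from the component fits.

    e_max is the mean transpiration of the well-watered plateau (light-
    filtered samples whose concurrent predawn potential exceeds
    ``e_plateau_psi``); hydraulic safety margins are psi_gs90 - P12/P50.
    """
    e_max = gc_fit.gsm * 1.27 / meteo.P_ATM  # fallback: Fickian flux at reference VPD
    if e_series is not None:
        e = np.asarray(e_series["e"], dtype=float)
        ok = np.asarray(e_series.get("light_ok", np.ones(e.size, bool)), dtype=bool)
        if psi_pd is not None:
            ok &= np.asarray(psi_pd, dtype=float) > e_plateau_psi
        if ok.any():
            e_max = float(np.nanmean(e[ok]))
    return GenotypeTraits.from_measured(
        name=name,
        gc_max=gc_fit.gsm,
        pgs50=gc_fit.pgs50,
        gs_slope=gc_fit.slp,
        g_night=g_night,
        g_min=g_min,
        pi0=pv.pi0,
        epsilon=pv.epsilon,
        p50_leaf=curve.p50,
        plc_slope=curve.slope,
        leaf_area=leaf_area,
        e_max=e_max,
        w_sat=w_sat,
    )
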