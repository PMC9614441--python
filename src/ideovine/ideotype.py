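"""In silico ideotype screening: random trait libraries, time-to-failure
ranking, elite selection, trait-syndrome clustering and trait-shift reports.

The screen draws trait combinations uniformly at random within the ranges
observed across the V. vinifera genotypes, simulates each combination to
leaf hydraulic failure under the standard no-rain dry-down, and keeps the
top-k performers ("Elites").  An extended mode additionally perturbs
architecture parameters within a ±fraction of their defaults ("Super
Elites").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .simulator import (
    DiurnalForcing,
    PlantArchitecture,
    SimConfig,
    Simulation,
    standard_forcing,
    vineyard_architecture,
)
from .types import GenotypeTraits

LN9 = math.log(9.0)

#: the eight screened hydraulic parameters
SCREENED_TRAITS = (
    "gc_max", "pgs50", "g_night", "g_min", "pi0", "epsilon", "p50_leaf", "plc_slope",
)

#: trait subset used for elite clustering (max conductance, closure
#: threshold, minimum conductance, embolism slope and threshold, safety margin)
CLUSTER_TRAITS = ("gc_max", "psi_gs90", "g_min", "plc_slope", "p50_leaf", "hsm_p12")


@dataclass
class TraitRanges:
    """Per-trait (low, high) sampling bounds plus optional architecture bounds."""

    bounds: dict[str, tuple[float, float]]
    gs_slope: float = 5.0  # closure-sigmoid slope held fixed per draw
    extended: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.bounds:
            raise ValueError("empty trait ranges")
        for name, (lo, hi) in {**self.bounds, **self.extended}.items():
            if lo > hi:
                raise ValueError(f"range for {name!r} has low > high")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        vinifera_only: bool = True,
        traits: Sequence[str] = SCREENED_TRAITS,
    ) -> "TraitRanges":
        """Bounds from a genotype trait table (restricted to V. vinifera
        entries by default, mirroring the screening protocol)."""
        df = table
        if vinifera_only:
            if "is_vinifera" not in df.columns:
                raise ValueError("table lacks an is_vinifera column")
            df = df[df["is_vinifera"].astype(bool)]
        if df.empty:
            raise ValueError("no rows available to derive ranges from")
        bounds = {t: (float(df[t].min()), float(df[t].max())) for t in traits}
        slope = float(df["gs_slope"].mean()) if "gs_slope" in df else 5.0
        return cls(bounds=bounds, gs_slope=slope)

    def with_extended(
        self,
        arch: PlantArchitecture,
        fraction: float = 0.5,
        parameters: Optional[Sequence[str]] = None,
        include_lai: bool = True,
    ) -> "TraitRanges":
        """Add architecture parameters varying ±``fraction`` of their defaults."""
        names = list(parameters or PlantArchitecture.PERTURBABLE)
        ext = {}
        for name in names:
            v = float(getattr(arch, name))
            ext[name] = (v * (1 - fraction), v * (1 + fraction))
        if include_lai:
            ext["lai_scale"] = (1 - fraction, 1 + fraction)
        return TraitRanges(bounds=dict(self.bounds), gs_slope=self.gs_slope, extended=ext)


@dataclass
class TraitLibrary:
    """Sampled trait combinations with their provenance."""

    samples: pd.DataFrame
    seed: int
    ranges: TraitRanges

    def __len__(self):
        return len(self.samples)


def sample_trait_library(ranges: TraitRanges, n: int, seed: int) -> TraitLibrary:
    """Independent uniform draws of each trait within its declared range."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in {**ranges.bounds, **ranges.extended}.items():
        cols[name] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    df = pd.DataFrame(cols)
    df["gs_slope"] = ranges.gs_slope
    return TraitLibrary(samples=df, seed=seed, ranges=ranges)


@dataclass
class EliteSet:
    """Top-k trait combinations by time to leaf hydraulic failure."""

    members: pd.DataFrame  # trait columns + days_to_failure + rank
    k: int

    @property
    def mean_days(self) -> float:
        return float(self.members["days_to_failure"].mean())


@dataclass
class ScreeningResult:
    library: TraitLibrary
    days: np.ndarray  # per-sample days to failure (inf = horizon exceeded)
    elites: EliteSet
    fraction_better_than_reference: Optional[float]
    reference_days: Optional[float]
    n_failed_runs: int

    @property
    def mean_days(self) -> float:
        finite = self.days[np.isfinite(self.days)]
        return float(finite.mean())


def evaluate_and_rank(
    library: TraitLibrary,
    k: int = 200,
    arch: Optional[PlantArchitecture] = None,
    forcing: Optional[DiurnalForcing] = None,
    reference: Optional[GenotypeTraits] = None,
    dt: float = 900.0,
    horizon_days: float = 400.0,
    config: Optional[SimConfig] = None,
    chunk_size: int = 4000,
) -> ScreeningResult:
    """Simulate every combination to failure and keep the top-k Elites.

    Evaluation is chunked (results are order-independent); combinations
    whose simulation errors out are recorded, excluded from ranking and
    counted.  When a ``reference`` genotype is given, the fraction of
    combinations outlasting it is reported.
    """
    arch = arch or vineyard_architecture()
    forcing = forcing or standard_forcing()
    df = library.samples
    days = np.full(len(df), np.nan)
    n_failed = 0
    for start in range(0, len(df), chunk_size):
        chunk = df.iloc[start : start + chunk_size]
        try:
            sim = Simulation(chunk.reset_index(drop=True), arch, config)
            sim.run(forcing, days=horizon_days, dt=dt)
            days[start : start + len(chunk)] = sim.days_to_failure()
        except (ValueError, FloatingPointError) as err:  # pragma: no cover - defensive
            warnings.warn(f"chunk starting at {start} failed: {err}")
            n_failed += len(chunk)
    valid = ~np.isnan(days)
    n_failed = int((~valid).sum())

    k_eff = min(k, int(valid.sum()))
    # top-k by time to failure; ties broken deterministically by sample index
    order = np.lexsort((np.arange(len(days)), -np.where(valid, days, -np.inf)))
    top = order[:k_eff]
    members = df.iloc[top].copy()
    members["days_to_failure"] = days[top]
    members["rank"] = np.arange(1, k_eff + 1)
    members["sample_index"] = top

    ref_days = None
    frac_better = None
    if reference is not None:
        from .simulator import simulate_to_failure

        ref_days = simulate_to_failure(
            reference, arch=arch, forcing=forcing, dt=dt,
            horizon_days=horizon_days, config=config,
        )
        frac_better = float(np.mean(days[valid] > ref_days))
    return ScreeningResult(
        library=library,
        days=days,
        elites=EliteSet(members=members.reset_index(drop=True), k=k_eff),
        fraction_better_than_reference=frac_better,
        reference_days=ref_days,
        n_failed_runs=n_failed,
    )


# ---------------------------------------------------------------------------
# Clustering of elite trait syndromes
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    linkage: np.ndarray
    k: int
    labels: np.ndarray
    cluster_means: pd.DataFrame
    wss: np.ndarray  # within-cluster sum of squares for k = 1..k_max


def derived_cluster_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add psi_gs90 and hsm_p12 columns derived from the sampled traits."""
    out = df.copy()
    if "psi_gs90" not in out and {"pgs50", "gs_slope"} <= set(out.columns):
        out["psi_gs90"] = out["pgs50"] - LN9 / out["gs_slope"]
    if (
        "hsm_p12" not in out
        and {"psi_gs90", "plc_slope", "p50_leaf"} <= set(out.columns)
    ):
        p12 = 50.0 / out["plc_slope"] + out["p50_leaf"]
        out["hsm_p12"] = out["psi_gs90"] - p12
    return out


def cluster_elites(
    elites: EliteSet | pd.DataFrame,
    trait_subset: Sequence[str] = CLUSTER_TRAITS,
    k_max: int = 10,
) -> ClusterResult:
    """Complete-linkage hierarchical clustering of z-scored elite traits.

    The number of clusters is chosen by the elbow of the within-cluster sum
    of squares over k = 1..k_max (largest second difference).  Constant
    trait columns are dropped with a warning (their z-score is undefined).
    """
    df = elites.members if isinstance(elites, EliteSet) else elites
    if len(df) < 3:
        raise ValueError("need at least 3 members to cluster")
    df = derived_cluster_columns(df)
    missing = [t for t in trait_subset if t not in df.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")
    x = df[list(trait_subset)].astype(float)
    sd = x.std(ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping constant trait columns {list(sd.index[~keep])}: z-score undefined"
        )
    x = x.loc[:, keep]
    if x.shape[1] == 0 or len(x.drop_duplicates()) == 1:
        z = x * 0.0
        labels = np.ones(len(df), dtype=int)
        return ClusterResult(
            zscores=z, linkage=np.empty((0, 4)), k=1, labels=labels,
            cluster_means=x.assign(cluster=1).groupby("cluster").mean(),
            wss=np.zeros(k_max),
        )
    z = (x - x.mean()) / x.std(ddof=0)
    link = hierarchy.linkage(z.to_numpy(), method="complete", metric="euclidean")
    k_max = min(k_max, len(df))
    wss = np.empty(k_max)
    labelings = {}
    zv = z.to_numpy()
    for k in range(1, k_max + 1):
        lab = hierarchy.fcluster(link, t=k, criterion="maxclust")
        labelings[k] = lab
        w = 0.0
        for c in np.unique(lab):
            pts = zv[lab == c]
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
        wss[k - 1] = w
    k_opt = _elbow(wss)
    labels = labelings[k_opt]
    means = (
        pd.DataFrame(zv, columns=z.columns)
        .assign(cluster=labels)
        .groupby("cluster")
        .mean()
    )
    return ClusterResult(zscores=z, linkage=link, k=k_opt, labels=labels,
                         cluster_means=means, wss=wss)


def _elbow(wss: np.ndarray) -> int:
    """Maximum-curvature point: largest second difference of WSS over k."""
    if wss[0] < 1e-12:
        return 1
    if wss.size < 3:
        return int(np.argmin(wss)) + 1
    d2 = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]  # curvature at k = 2..k_max-1
    return int(np.argmax(d2)) + 2


# ---------------------------------------------------------------------------
# Trait-shift summaries
# ---------------------------------------------------------------------------

def summarize_trait_shifts(
    elites: EliteSet | pd.DataFrame,
    reference_means: pd.Series | dict,
    threshold_pct: float = 5.0,
) -> pd.DataFrame:
    """Percent deviation of elite trait means from reference (Vitis) means.

    Traits whose mean shift exceeds ``threshold_pct`` in magnitude are
    flagged — these are the traits that define the drought-tolerant
    syndrome.  Raises if a reference trait is absent from the elites.
    """
    df = elites.members if isinstance(elites, EliteSet) else elites
    df = derived_cluster_columns(df)
    ref = pd.Series(reference_means, dtype=float)
    missing = [t for t in ref.index if t not in df.columns]
    if missing:
        raise ValueError(f"elite table lacks traits: {missing}")
    rows = []
    for trait, ref_mean in ref.items():
        elite_mean = float(df[trait].mean())
        shift = (elite_mean - ref_mean) / abs(ref_mean) * 100.0 if ref_mean != 0 else np.nan
        rows.append(
            {
                "trait": trait,
                "elite_mean": elite_mean,
                "reference_mean": float(ref_mean),
                "shift_pct": shift,
                "flagged": bool(abs(shift) > threshold_pct) if np.isfinite(shift) else False,
            }
        )
    return pd.DataFrame(rows)
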