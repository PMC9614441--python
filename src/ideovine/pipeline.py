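"""End-to-end screening pipeline with manifest-based provenance and resume.

Stages: load the genotype trait table -> derive V. vinifera trait ranges ->
sample and screen a random library -> cluster the elites -> summarise trait
shifts -> (optionally) project the reference genotype and the elite-mean
ideotype over a weather series.  Every output CSV is accompanied by a JSON
manifest recording the config hash, seed and per-stage status, which also
makes a rerun resumable from the last completed stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as iio
from .climate import decade_summary, load_daily_weather, run_multiyear_projection
from .ideotype import (
    TraitRanges,
    cluster_elites,
    derived_cluster_columns,
    evaluate_and_rank,
    sample_trait_library,
    summarize_trait_shifts,
)
from .simulator import Simulation, vineyard_architecture, standard_forcing
from .types import PhenologyCalendar


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serialisable)."""

    out_dir: str = "ideo_run"
    seed: int = 1
    library_n: int = 50000
    elite_k: int = 200
    dt: float = 900.0
    horizon_days: float = 400.0
    failure_plc: float = 99.5
    trait_table: Optional[str] = None  # CSV path; packaged fixture when None
    reference_genotype: str = "Grenache"
    extended: bool = False
    extended_fraction: float = 0.5
    shift_threshold_pct: float = 5.0
    weather: Optional[str] = None  # daily weather CSV for the projection stage
    stages: tuple = ("screen", "cluster", "shifts", "project")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.trait_table and not Path(cfg.trait_table).exists():
            raise FileNotFoundError(cfg.trait_table)
        if cfg.weather and not Path(cfg.weather).exists():
            raise FileNotFoundError(cfg.weather)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": _version(),
        "stages": {},
        "outputs": {},
    }
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest = old  # resume: completed stages are skipped below

    def done(stage: str) -> bool:
        info = manifest["stages"].get(stage)
        return bool(info and info.get("status") == "complete")

    def finish(stage: str, outputs: dict):
        manifest["stages"][stage] = {"status": "complete", "elapsed_s": round(time.time() - t0, 2)}
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})
        manifest_path.write_text(json.dumps(manifest, indent=2))

    table = iio.load_genotype_table(config.trait_table)
    arch = vineyard_architecture()
    forcing = standard_forcing()
    ranges = TraitRanges.from_table(table)
    if config.extended:
        ranges = ranges.with_extended(arch, fraction=config.extended_fraction)
    reference = iio.genotype(config.reference_genotype, table)

    screening = None
    if "screen" in config.stages and not done("screen"):
        t0 = time.time()
        lib = sample_trait_library(ranges, config.library_n, seed=config.seed)
        screening = evaluate_and_rank(
            lib, k=config.elite_k, arch=arch, forcing=forcing,
            reference=reference, dt=config.dt, horizon_days=config.horizon_days,
        )
        lib_path = out / "library.csv"
        lib.samples.assign(days_to_failure=screening.days).to_csv(lib_path, index=False)
        elites_path = out / "elites.csv"
        screening.elites.members.to_csv(elites_path, index=False)
        summary_path = out / "screen_summary.json"
        summary_path.write_text(json.dumps({
            "library_n": len(lib),
            "library_mean_days": screening.mean_days,
            "elite_mean_days": screening.elites.mean_days,
            "reference_genotype": config.reference_genotype,
            "reference_days": screening.reference_days,
            "fraction_better_than_reference": screening.fraction_better_than_reference,
            "n_failed_runs": screening.n_failed_runs,
        }, indent=2))
        finish("screen", {"library": lib_path, "elites": elites_path, "screen_summary": summary_path})

    elites_csv = out / "elites.csv"
    if "cluster" in config.stages and not done("cluster") and elites_csv.exists():
        t0 = time.time()
        elites = pd.read_csv(elites_csv)
        res = cluster_elites(elites)
        labels_path = out / "elite_clusters.csv"
        derived_cluster_columns(elites).assign(cluster=res.labels).to_csv(labels_path, index=False)
        heat_path = out / "cluster_zscores.csv"
        res.zscores.assign(cluster=res.labels).to_csv(heat_path, index=False)
        finish("cluster", {"elite_clusters": labels_path, "cluster_zscores": heat_path})

    if "shifts" in config.stages and not done("shifts") and elites_csv.exists():
        t0 = time.time()
        elites = pd.read_csv(elites_csv)
        ref_means = derived_cluster_columns(
            table[table["is_vinifera"].astype(bool)]
        )[list(ranges.bounds) + ["psi_gs90", "hsm_p12"]].mean()
        shifts = summarize_trait_shifts(elites, ref_means, config.shift_threshold_pct)
        shifts_path = out / "trait_shifts.csv"
        shifts.to_csv(shifts_path, index=False)
        finish("shifts", {"trait_shifts": shifts_path})

    if "project" in config.stages and not done("project") and config.weather:
        t0 = time.time()
        weather = load_daily_weather(config.weather)
        seasons = run_multiyear_projection(reference, weather, PhenologyCalendar())
        seasons_path = out / f"seasons_{config.reference_genotype}.csv"
        seasons.to_csv(seasons_path, index=False)
        decades_path = out / f"decades_{config.reference_genotype}.csv"
        decade_summary(seasons).to_csv(decades_path, index=False)
        finish("project", {"seasons": seasons_path, "decades": decades_path})

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
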