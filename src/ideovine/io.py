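"""CSV readers/writers and the packaged genotype trait table.

All tabular interfaces are plain UTF-8 CSV with documented column names;
timestamps are seconds-since-start or ISO-8601 dates.  The packaged
genotype table is a synthetic stand-in: no measured accessions are
distributed, so the shipped values are constructed to be physiologically
plausible for Vitis and internally consistent (every derived column honours
the GenotypeTraits invariants), with the qualitative contrasts reported for
the named genotypes (drought-tolerant Grenache/Vidadillo: low maximum and
minimum conductance, early stomatal closure; profligate Syrah/Semillon:
high water use, later closure).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

from .types import GenotypeTraits, LysimeterSeries, PVSeries

FIXTURE_NAME = "vitis_traits_synthetic.csv"

#: measured inputs of the synthetic genotype table
#: (gc_max, pgs50, gs_slope, g_night, g_min, pi0, epsilon, p50_leaf, plc_slope, leaf_area)
_SYNTHETIC_GENOTYPES: dict[str, tuple] = {
    # V. vinifera cultivars
    "Grenache":     (200.0, -0.55, 5.0, 14.0, 2.15, -0.95,  9.0, -1.80, 55.0, 0.15),
    "Vidadillo":    (180.0, -0.62, 5.5, 12.0, 2.25, -1.00, 10.0, -1.90, 60.0, 0.15),
    "Syrah":        (260.0, -1.00, 4.5, 20.0, 3.5, -1.10, 11.0, -1.75, 75.0, 0.15),
    "Semillon":     (270.0, -1.05, 4.0, 22.0, 3.8, -1.25, 12.0, -2.30, 80.0, 0.15),
    "Yiannoudi":    (230.0, -0.85, 5.0, 18.0, 1.9, -1.05, 10.5, -2.00, 65.0, 0.15),
    # non-vinifera Vitis species
    "V. candicans": (210.0, -0.75, 5.0, 16.0, 2.6, -1.00,  9.5, -1.70, 60.0, 0.15),
    "V. labrusca":  (200.0, -0.70, 5.5, 15.0, 2.2, -1.05, 10.0, -1.95, 58.0, 0.15),
    "RGM":          (240.0, -0.90, 4.8, 19.0, 3.2, -1.15, 11.5, -1.85, 70.0, 0.15),
    "V. rupestris": (250.0, -0.95, 4.6, 21.0, 3.4, -1.20, 11.0, -1.70, 72.0, 0.15),
}
_VINIFERA = {"Grenache", "Vidadillo", "Syrah", "Semillon", "Yiannoudi"}

TRAIT_TABLE_COLUMNS = [
    "genotype", "is_vinifera", "gc_max", "e_max", "pgs50", "gs_slope", "psi_gs90",
    "g_night", "g_min", "pi0", "epsilon", "psi_tlp", "c_ft", "c_tlp",
    "p50_leaf", "p12_leaf", "p88_leaf", "plc_slope", "hsm_p12", "hsm_p50",
    "leaf_area",
]


def synthetic_vitis_table() -> pd.DataFrame:
    """Build the synthetic genotype trait table (derived columns computed)."""
    rows = []
    for name, vals in _SYNTHETIC_GENOTYPES.items():
        gc_max, pgs50, slp, g_night, g_min, pi0, eps, p50, plc_slp, la = vals
        t = GenotypeTraits.from_measured(
            name=name, gc_max=gc_max, pgs50=pgs50, gs_slope=slp,
            g_night=g_night, g_min=g_min, pi0=pi0, epsilon=eps,
            p50_leaf=p50, plc_slope=plc_slp, leaf_area=la,
        )
        row = {"genotype": name, "is_vinifera": name in _VINIFERA}
        row.update({k: v for k, v in t.to_dict().items() if k != "name"})
        rows.append(row)
    return pd.DataFrame(rows)[TRAIT_TABLE_COLUMNS]


def load_genotype_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a genotype trait table (the packaged synthetic fixture by default)."""
    if path is None:
        with resources.as_file(resources.files("ideovine.data") / FIXTURE_NAME) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")
    return df


def traits_from_row(row: pd.Series) -> GenotypeTraits:
    """Rehydrate a GenotypeTraits object from one trait-table row."""
    kwargs = {c: row[c] for c in TRAIT_TABLE_COLUMNS if c not in ("genotype", "is_vinifera")}
    return GenotypeTraits(name=str(row["genotype"]), **kwargs)


def genotype(name: str, table: pd.DataFrame | None = None) -> GenotypeTraits:
    """Look one genotype up by name in a trait table."""
    df = table if table is not None else load_genotype_table()
    hit = df[df["genotype"] == name]
    if hit.empty:
        raise KeyError(f"genotype {name!r} not in table")
    return traits_from_row(hit.iloc[0])


# ---------------------------------------------------------------------------
# Measurement series CSV round-trips
# ---------------------------------------------------------------------------

def write_lysimeter_csv(series: LysimeterSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.time,
            "weight_g": series.weight,
            "air_temp_c": series.air_temp,
            "rh_pct": series.rh,
            "ppfd": series.ppfd,
        }
    ).to_csv(path, index=False)
    if series.psi_pd is not None:
        psi_path = Path(path).with_suffix(".psi_pd.csv")
        pd.DataFrame({"time_s": series.psi_pd_time, "psi_pd_mpa": series.psi_pd}).to_csv(
            psi_path, index=False
        )


def read_lysimeter_csv(path: str | Path) -> LysimeterSeries:
    df = pd.read_csv(path)
    psi_path = Path(path).with_suffix(".psi_pd.csv")
    psi_t = psi_v = None
    if psi_path.exists():
        psi = pd.read_csv(psi_path)
        psi_t, psi_v = psi["time_s"].to_numpy(), psi["psi_pd_mpa"].to_numpy()
    return LysimeterSeries(
        time=df["time_s"].to_numpy(),
        weight=df["weight_g"].to_numpy(),
        air_temp=df["air_temp_c"].to_numpy(),
        rh=df["rh_pct"].to_numpy(),
        ppfd=df["ppfd"].to_numpy(),
        psi_pd_time=psi_t,
        psi_pd=psi_v,
    )


def write_pv_csv(pv: PVSeries, path: str | Path) -> None:
    df = pd.DataFrame({"psi_leaf_mpa": pv.psi_leaf, "mass_g": pv.mass})
    df["turgid_weight_g"] = pv.turgid_weight
    df["dry_weight_g"] = pv.dry_weight
    df.to_csv(path, index=False)


def read_pv_csv(path: str | Path) -> PVSeries:
    df = pd.read_csv(path)
    return PVSeries(
        psi_leaf=df["psi_leaf_mpa"].to_numpy(),
        mass=df["mass_g"].to_numpy(),
        turgid_weight=float(df["turgid_weight_g"].iloc[0]),
        dry_weight=float(df["dry_weight_g"].iloc[0]),
    )


def read_image_directory(path: str | Path):
    """Yield grayscale frames from a directory of PNG/TIFF files in filename
    order (streaming; frames are not all held in memory)."""
    import imageio.v3 as iio

    files = sorted(
        p for p in Path(path).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if len(files) < 2:
        raise ValueError("image directory must contain at least two frames")
    for f in files:
        frame = iio.imread(f)
        if frame.ndim == 3:
            frame = frame.mean(axis=2)
        yield np.asarray(frame)
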