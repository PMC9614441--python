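"""Trait-library sampling, screening, clustering and shift summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ideovine as iv
from ideovine.ideotype import (
    CLUSTER_TRAITS,
    TraitRanges,
    cluster_elites,
    derived_cluster_columns,
    evaluate_and_rank,
    sample_trait_library,
    summarize_trait_shifts,
)
from ideovine.simulator import Simulation, vineyard_architecture


@pytest.fixture(scope="module")
def ranges(table):
    return TraitRanges.from_table(table)


class TestSampling:
    def test_samples_respect_bounds(self, ranges):
        lib = sample_trait_library(ranges, 1000, seed=3)
        for name, (lo, hi) in ranges.bounds.items():
            col = lib.samples[name]
            assert col.min() >= lo and col.max() <= hi

    def test_same_seed_identical_library(self, ranges):
        a = sample_trait_library(ranges, 500, seed=11).samples
        b = sample_trait_library(ranges, 500, seed=11).samples
        pd.testing.assert_frame_equal(a, b)

    def test_margins_are_uniform(self, ranges):
        lib = sample_trait_library(ranges, 10000, seed=7)
        for name, (lo, hi) in ranges.bounds.items():
            u = (lib.samples[name] - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            TraitRanges(bounds={})

    def test_vinifera_restriction(self, table):
        r_all = TraitRanges.from_table(table, vinifera_only=False)
        r_vin = TraitRanges.from_table(table, vinifera_only=True)
        vin = table[table["is_vinifera"]]
        for name, (lo, hi) in r_vin.bounds.items():
            assert lo == float(vin[name].min()) and hi == float(vin[name].max())
        # the species add range beyond vinifera for at least one trait
        assert any(
            r_all.bounds[n] != r_vin.bounds[n] for n in r_vin.bounds
        )

    def test_extended_mode_adds_architecture_bounds(self, ranges):
        arch = vineyard_architecture()
        ext = ranges.with_extended(arch, fraction=0.5)
        assert "k_root" in ext.extended
        lo, hi = ext.extended["k_root"]
        assert lo == pytest.approx(0.5 * arch.k_root)
        assert hi == pytest.approx(1.5 * arch.k_root)


class TestScreening:
    def test_k_equal_n_returns_whole_library(self, ranges):
        lib = sample_trait_library(ranges, 6, seed=1)
        res = evaluate_and_rank(lib, k=6, dt=2400.0, horizon_days=250.0)
        assert len(res.elites.members) == 6

    def test_hand_built_ordering_by_water_use(self, table):
        """Three combinations differing only in maximum conductance rank in
        reverse order of their transpiration rates."""
        row = iv.io.genotype("Syrah", table)
        base = {c: getattr(row, c) for c in Simulation.TRAIT_COLS}
        combos = pd.DataFrame([dict(base, gc_max=g) for g in (180.0, 230.0, 280.0)])
        lib = sample_trait_library(TraitRanges(bounds={"gc_max": (1, 1)}), 1, 0)
        lib.samples = combos
        res = evaluate_and_rank(lib, k=3, dt=1800.0, horizon_days=250.0)
        ranked_gcmax = res.elites.members.sort_values("rank")["gc_max"].tolist()
        assert ranked_gcmax == [180.0, 230.0, 280.0]
        assert res.elites.mean_days >= np.mean(res.days)

    def test_fraction_better_matches_brute_force_count(self, ranges, grenache):
        lib = sample_trait_library(ranges, 12, seed=5)
        res = evaluate_and_rank(
            lib, k=3, reference=grenache, dt=2400.0, horizon_days=250.0
        )
        finite = res.days[np.isfinite(res.days)]
        assert res.fraction_better_than_reference == pytest.approx(
            np.sum(finite > res.reference_days) / finite.size
        )


class TestClustering:
    def test_identical_members_collapse_to_one_cluster(self):
        df = pd.DataFrame(
            {t: np.full(12, v) for t, v in zip(CLUSTER_TRAITS, [200, -1, 3, 60, -2, 1])}
        )
        with pytest.warns(UserWarning):
            res = cluster_elites(df)
        assert res.k == 1

    def test_two_planted_blobs_recovered(self, rng):
        n = 40
        blob = lambda mu: rng.normal(mu, 0.05, size=(n, len(CLUSTER_TRAITS)))
        x = np.vstack([blob(0.0), blob(3.0)])
        df = pd.DataFrame(x, columns=CLUSTER_TRAITS)
        res = cluster_elites(df, k_max=8)
        assert res.k == 2
        labels = res.labels
        assert len(set(labels[:n])) == 1
        assert len(set(labels[n:])) == 1
        assert labels[0] != labels[-1]

    def test_zscore_columns_standardised(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(30, len(CLUSTER_TRAITS))) * [10, 1, 0.5, 20, 2, 1] + 5,
            columns=CLUSTER_TRAITS,
        )
        res = cluster_elites(df)
        assert np.allclose(res.zscores.mean(), 0.0, atol=1e-12)
        assert np.allclose(res.zscores.std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(20, len(CLUSTER_TRAITS))), columns=CLUSTER_TRAITS
        )
        df["g_min"] = 2.5
        with pytest.warns(UserWarning, match="g_min"):
            res = cluster_elites(df)
        assert "g_min" not in res.zscores.columns

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError):
            cluster_elites(pd.DataFrame({t: [1.0, 2.0] for t in CLUSTER_TRAITS}))


class TestTraitShifts:
    def test_identical_elites_have_zero_shift(self):
        ref = {"gc_max": 200.0, "g_min": 3.0}
        df = pd.DataFrame({"gc_max": [200.0] * 5, "g_min": [3.0] * 5,
                           "pgs50": [-0.8] * 5, "gs_slope": [5.0] * 5,
                           "plc_slope": [60.0] * 5, "p50_leaf": [-2.0] * 5})
        out = summarize_trait_shifts(df, ref)
        assert np.allclose(out["shift_pct"], 0.0)
        assert not out["flagged"].any()

    def test_shift_arithmetic(self):
        df = pd.DataFrame({"gc_max": [160.0] * 4, "pgs50": [-0.8] * 4,
                           "gs_slope": [5.0] * 4, "plc_slope": [60.0] * 4,
                           "p50_leaf": [-2.0] * 4})
        out = summarize_trait_shifts(df, {"gc_max": 200.0}, threshold_pct=5.0)
        assert out.loc[0, "shift_pct"] == pytest.approx(-20.0)
        assert bool(out.loc[0, "flagged"])

    def test_missing_trait_rejected(self):
        df = pd.DataFrame({"gc_max": [1.0] * 3})
        with pytest.raises(ValueError):
            summarize_trait_shifts(df, {"nope": 1.0})

    def test_derived_columns_added(self):
        df = pd.DataFrame({"pgs50": [-0.8], "gs_slope": [5.0],
                           "plc_slope": [60.0], "p50_leaf": [-2.0]})
        out = derived_cluster_columns(df)
        assert out["psi_gs90"].iloc[0] == pytest.approx(-0.8 - np.log(9) / 5)
        assert out["hsm_p12"].iloc[0] == pytest.approx(
            out["psi_gs90"].iloc[0] - (50.0 / 60.0 - 2.0)
        )
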