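"""Metaprofiles, permutation enrichment and GRO-seq dependence."""

import numpy as np
import pytest

from ernakit.core import CoverageTrack, GenomicInterval
from ernakit.quantify import CountMatrix
from ernakit.simulate import SimulationConfig, simulate_annotation, simulate_counts
from ernakit.validation import (
    groseq_dependence,
    metaprofile,
    permutation_enrichment,
)


def constant_track(value, size=100_000, chrom="chrT"):
    return CoverageTrack.from_runs([(chrom, 0, size, value)])


class TestMetaprofile:
    def test_constant_coverage_gives_flat_profile(self):
        mp = metaprofile(constant_track(3.5), [("chrT", 50_000)], flank=500)
        assert np.allclose(mp.mean_signal, 3.5)
        assert mp.n_regions == 1

    def test_unit_signal_at_centers_lands_in_center_bin(self):
        centers = [("chrT", c) for c in (10_000, 20_000, 30_000)]
        track = CoverageTrack.from_runs(
            [("chrT", c, c + 1, 1.0) for _, c in centers]
        )
        mp = metaprofile(track, centers, flank=100, bin=10)
        expected = np.zeros(20)
        expected[10] = 0.1  # 1 covered base / bin width 10
        assert np.allclose(mp.mean_signal, expected)

    def test_matches_slice_and_average_oracle(self):
        rng = np.random.default_rng(16)
        runs = [("chrT", i * 50, i * 50 + 50, float(v))
                for i, v in enumerate(rng.integers(0, 10, 2000))]
        track = CoverageTrack.from_runs(runs)
        centers = [("chrT", int(c)) for c in rng.integers(1000, 99_000, 20)]
        flank, bin_ = 500, 10
        mp = metaprofile(track, centers, flank, bin_)
        slices = np.array([
            track.values("chrT", c - flank, c + flank) for _, c in centers
        ])
        expected = slices.mean(axis=0).reshape(-1, bin_).mean(axis=1)
        assert np.allclose(mp.mean_signal, expected)

    def test_edge_regions_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            mp = metaprofile(constant_track(1.0),
                             [("chrT", 100), ("chrT", 50_000)], flank=500)
        assert mp.n_regions == 1

    def test_all_regions_unusable_errors(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                metaprofile(constant_track(1.0), [("chrT", 10)], flank=500)

    def test_symmetric_signal_gives_symmetric_profile(self):
        center = 50_000
        runs = [("chrT", center - w, center + w, 1.0) for w in (0,)]
        track = CoverageTrack.from_runs([("chrT", center - 200, center + 200, 2.0)])
        mp = metaprofile(track, [("chrT", center)], flank=500, bin=10)
        assert np.allclose(mp.mean_signal, mp.mean_signal[::-1])


def regions(starts, length=100, chrom="chrT"):
    return [GenomicInterval(chrom, s, s + length) for s in starts]


class TestPermutationEnrichment:
    def test_targets_equal_pool_is_null(self):
        track = constant_track(1.0)
        targets = regions(range(0, 10_000, 1000))
        res = permutation_enrichment(track, targets, targets, n_perm=50, seed=1)
        assert res.p_value == 1.0
        assert res.fold == pytest.approx(1.0)

    def test_signal_only_in_targets_attains_lower_bound(self):
        targets = regions([1000, 3000, 5000])
        pool = regions(range(10_000, 60_000, 1000))
        track = CoverageTrack.from_runs(
            [("chrT", t.start, t.end, 5.0) for t in targets]
        )
        res = permutation_enrichment(track, targets, pool, n_perm=99, seed=2)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(17)
        runs = [("chrT", i * 100, i * 100 + 100, float(v))
                for i, v in enumerate(rng.integers(0, 20, 1000))]
        track = CoverageTrack.from_runs(runs)
        targets = regions(rng.integers(0, 90_000, 10))
        pool = regions(rng.integers(0, 90_000, 50))
        a = permutation_enrichment(track, targets, pool, n_perm=200, seed=7)
        b = permutation_enrichment(track, targets, pool, n_perm=200, seed=7)
        assert a.observed_mean == b.observed_mean
        assert (a.null_means == b.null_means).all()
        assert a.p_value == b.p_value

    def test_pool_smaller_than_targets_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            permutation_enrichment(constant_track(1.0),
                                   regions([0, 1000]), regions([5000]))

    def test_null_p_values_super_uniform(self):
        # signal independent of region identity: p < 0.05 rarely
        rng = np.random.default_rng(18)
        runs = [("chrT", i * 100, i * 100 + 100, float(v))
                for i, v in enumerate(rng.integers(0, 20, 1000))]
        track = CoverageTrack.from_runs(runs)
        pool = regions(np.arange(0, 99_000, 500))
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            r = np.random.default_rng(1000 + seed)
            idx = r.choice(len(pool), size=15, replace=False)
            targets = [pool[i] for i in idx]
            res = permutation_enrichment(track, targets, pool,
                                         n_perm=99, seed=seed)
            hits += res.p_value < 0.05
        assert hits / n_runs <= 0.07


class TestGroseqDependence:
    def make_cm(self, group_means, n=2, n_feat=5, n_anchor=20):
        """group_means: dict (genotype, condition) -> mean count.

        ``n_anchor`` constant features keep median-of-ratios size
        factors anchored at 1 so the planted effect is not normalized
        away (as it would be if every feature changed together).
        """
        sample_ids, condition, genotype, cols = [], [], [], []
        for (gt, cond), mean in group_means.items():
            for k in range(n):
                sample_ids.append(f"{gt}_{cond}_{k}")
                condition.append(cond)
                genotype.append(gt)
                cols.append(np.concatenate([
                    np.full(n_feat, int(mean)), np.full(n_anchor, 100)
                ]))
        return CountMatrix(
            feature_ids=[f"e{i}" for i in range(n_feat)]
            + [f"anchor{i}" for i in range(n_anchor)],
            sample_ids=sample_ids,
            counts=np.column_stack(cols).astype(np.int64),
            condition=condition,
            genotype=genotype,
        )

    def test_equal_group_means_give_zero_delta(self):
        cm = self.make_cm({(g, c): 100 for g in ("flox", "lko")
                           for c in ("vehicle", "treated")})
        summary = groseq_dependence(cm, [f for f in cm.feature_ids if f.startswith('e')])
        assert summary.delta == pytest.approx(0.0)

    def test_eightfold_flox_only_induction(self):
        cm = self.make_cm({
            ("flox", "vehicle"): 1000, ("flox", "treated"): 8000,
            ("lko", "vehicle"): 1000, ("lko", "treated"): 1000,
        })
        summary = groseq_dependence(cm, [f for f in cm.feature_ids if f.startswith('e')], eps=1e-9)
        assert np.allclose(summary.lfc_flox, 3.0, atol=1e-4)
        assert np.allclose(summary.lfc_lko, 0.0, atol=1e-4)
        assert summary.delta == pytest.approx(3.0, abs=1e-4)

    def test_missing_group_errors(self):
        cm = self.make_cm({("flox", "vehicle"): 100, ("flox", "treated"): 100})
        with pytest.raises(ValueError, match="missing group"):
            groseq_dependence(cm, cm.feature_ids)

    def test_synthetic_receptor_dependence(self):
        config = SimulationConfig()
        _, _, _, truth = simulate_annotation(config, seed=5)
        cm = simulate_counts(truth, config, assay="groseq", seed=5)
        induced = [r.region_id for r in truth if r.label == "induced"]
        summary = groseq_dependence(cm, induced, n_perm=500, seed=5)
        assert summary.delta > 1.0
        assert abs(np.median(summary.lfc_lko)) < 0.5
        assert summary.p_value < 0.05
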