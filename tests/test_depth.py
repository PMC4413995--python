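"""Depth -> CN: binning rules, pooling, GC correction, calibration."""

import numpy as np
import pandas as pd
import pytest

from suscape import depth as dp
from suscape import simulate as sim


def _grid_from_arrays(unmasked, gc=None, bin_size=1000):
    chrom_sizes = {"chr1": len(unmasked) * bin_size}

    class G:
        pass

    g = G()
    g.bin_size = bin_size
    g.chrom_sizes = chrom_sizes
    g.unmasked = {"chr1": np.asarray(unmasked)}
    g.gc = {"chr1": np.asarray(gc) if gc is not None else np.full(len(unmasked), 0.4)}
    return dp.build_bins(g)


class TestBuildBins:
    @pytest.mark.parametrize("unmasked,kept", [(0, False), (299, False), (300, True), (1000, True)])
    def test_min_unmasked_boundary(self, unmasked, kept):
        grid = _grid_from_arrays([1000, unmasked, 1000])
        starts = set(grid.bins["start"])
        assert (1000 in starts) == kept

    def test_unmasked_chromosome_keeps_every_bin(self):
        grid = _grid_from_arrays([1000] * 10)
        assert len(grid) == 10

    def test_mask_intervals_are_unioned_and_bounded(self):
        mask = {"chr1": np.array([[0, 600], [400, 900]])}  # overlap: union 0-900
        grid = dp.build_bins(mask=mask, chrom_sizes={"chr1": 3000}, bin_size=1000)
        assert 0 not in set(grid.bins["start"])  # only 100 unmasked bases
        assert {1000, 2000} <= set(grid.bins["start"])
        with pytest.raises(ValueError):
            dp.build_bins(mask={"chr1": np.array([[0, 5000]])}, chrom_sizes={"chr1": 3000})

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            dp.build_bins(mask={}, chrom_sizes={"chr1": 1000}, bin_size=0)

    def test_blacklist_drops_chromosome(self, small_genome):
        full = dp.build_bins(small_genome)
        none = dp.build_bins(small_genome, blacklist=("chr1",))
        assert len(full) > 0 and len(none) == 0

    def test_run_starts_break_at_dropped_bins(self):
        grid = _grid_from_arrays([1000, 1000, 0, 1000])
        assert list(grid.run_starts()) == [True, False, True]


class TestPooling:
    def test_pooled_depth_is_sum_and_commutative(self):
        a = dp.DepthTrack("p", np.array([5.0, 1.0]))
        b = dp.DepthTrack("p", np.array([7.0, 2.0]))
        assert np.array_equal(dp.pool_population([a, b]).depth, [12.0, 3.0])
        assert np.array_equal(dp.pool_population([b, a]).depth, [12.0, 3.0])

    def test_single_individual_identity(self):
        a = dp.DepthTrack("p", np.array([5.0, 1.0]))
        assert np.array_equal(dp.pool_population([a]).depth, a.depth)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            dp.pool_population([dp.DepthTrack("p", np.ones(3)), dp.DepthTrack("p", np.ones(4))])


class TestGCCorrection:
    def test_factors_match_hand_arithmetic(self):
        """Stratum means 8 and 10 around a global reference mean of 9 give
        factors 1.125 and 0.9."""
        n = 200
        gc = np.array([0.405] * n + [0.505] * n)
        depth = np.array([8.0] * n + [10.0] * n)
        grid = _grid_from_arrays([1000] * 2 * n, gc)
        model = dp.fit_gc_model(dp.DepthTrack("p", depth), grid, min_bins=100)
        f_low = model.factors[model.stratum(np.array([0.405]))[0]]
        f_high = model.factors[model.stratum(np.array([0.505]))[0]]
        assert np.isclose(f_low, 1.125)
        assert np.isclose(f_high, 0.9)

    def test_flat_depth_gives_unit_factors(self):
        gc = np.linspace(0.3, 0.6, 400)
        grid = _grid_from_arrays([1000] * 400, gc)
        model, corrected = dp.fit_and_apply_gc_correction(dp.DepthTrack("p", np.full(400, 6.0)), grid, min_bins=20)
        assert np.allclose(model.factors, 1.0)
        assert np.allclose(corrected.depth, 6.0)

    def test_known_simulated_bias_is_removed(self, small_genome):
        """With the default bias curve active, post-correction per-stratum
        means agree within 2% for populated strata."""
        cfg = sim.ReadDepthSimConfig(coverage=20.0, seed=31)
        track_bins = sim.simulate_depth_track(small_genome, None, "p", cfg)
        grid = dp.build_bins(small_genome)
        raw = dp.track_from_bins(grid, track_bins, "p")
        model, corrected = dp.fit_and_apply_gc_correction(raw, grid)
        gc = grid.bins["gc"].to_numpy()
        strata = model.stratum(gc)
        means = []
        for s in np.unique(strata):
            sel = strata == s
            if sel.sum() >= model.min_bins:
                means.append(np.mean(corrected.depth[sel]))
        means = np.asarray(means)
        assert len(means) >= 3
        assert means.max() / means.min() - 1 < 0.02

    def test_reference_mean_preserved(self, small_genome):
        cfg = sim.ReadDepthSimConfig(coverage=12.0, seed=32)
        grid = dp.build_bins(small_genome)
        raw = dp.track_from_bins(grid, sim.simulate_depth_track(small_genome, None, "p", cfg), "p")
        reference = np.zeros(len(grid), dtype=bool)
        reference[:: 2] = True
        model, corrected = dp.fit_and_apply_gc_correction(raw, grid, reference)
        before = np.mean(raw.depth[reference])
        after = np.mean(corrected.depth[reference])
        assert abs(after / before - 1) < 1e-3

    def test_empty_reference_rejected(self):
        grid = _grid_from_arrays([1000] * 10)
        with pytest.raises(ValueError):
            dp.fit_gc_model(dp.DepthTrack("p", np.ones(10)), grid, np.zeros(10, dtype=bool))


class TestCalibration:
    def _seed_regions(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60_000]})

    def test_homogeneous_diploid_genome(self):
        grid = _grid_from_arrays([1000] * 100)
        track = dp.DepthTrack("p", np.full(100, 10.0))
        cal = dp.calibrate_diploid(track, grid, self._seed_regions())
        assert cal.stage1_d2 == 10.0 and cal.d2 == 10.0

    def test_contaminated_seed_regions_recovered_by_stage_two(self):
        """A CN=4 segment inside the seed set inflates stage 1; stage 2's
        re-classification pulls d2 back toward the true diploid mean."""
        depth = np.full(200, 10.0)
        depth[10:30] = 20.0  # CN 4 inside the seed window
        rng = np.random.default_rng(0)
        depth += rng.normal(0, 0.3, 200)
        grid = _grid_from_arrays([1000] * 200)
        seeds = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60_000]})
        cal = dp.calibrate_diploid(dp.DepthTrack("p", depth), grid, seeds)
        true_diploid = depth[np.concatenate([np.arange(10), np.arange(30, 200)])].mean()
        assert abs(cal.d2 - true_diploid) < abs(cal.stage1_d2 - true_diploid)

    def test_scale_equivariance_of_cn(self):
        rng = np.random.default_rng(1)
        depth = rng.gamma(50, 0.2, 300)
        grid = _grid_from_arrays([1000] * 300)
        seeds = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [80_000]})
        cn1 = dp.estimate_cn(dp.DepthTrack("p", depth), dp.calibrate_diploid(dp.DepthTrack("p", depth), grid, seeds))
        scaled = dp.DepthTrack("p", depth * 3.7)
        cn2 = dp.estimate_cn(scaled, dp.calibrate_diploid(scaled, grid, seeds))
        assert np.allclose(cn1.cn, cn2.cn)

    def test_too_few_seed_bins_rejected(self):
        grid = _grid_from_arrays([1000] * 100)
        seeds = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        with pytest.raises(ValueError):
            dp.calibrate_diploid(dp.DepthTrack("p", np.ones(100)), grid, seeds)


class TestEstimateCN:
    def test_simple_ratios(self):
        cal = dp.DiploidCalibration(10.0, np.ones(3, dtype=bool), 10.0)
        cn = dp.estimate_cn(dp.DepthTrack("p", np.array([15.0, 0.0, 10.0])), cal)
        assert np.allclose(cn.cn, [3.0, 0.0, 2.0])

    def test_simulated_cn6_locus_recovered(self, cohort):
        land, tracks = cohort["landscape"], cohort["cn_tracks"]
        bs = cohort["genome"].bin_size
        grid = cohort["grid"]
        found = False
        for i, locus in land.loci.iterrows():
            for j, pop in enumerate(land.populations):
                if land.cn[i, j] == 6:
                    sel = (grid.bins["chrom"] == locus["chrom"]) & (
                        grid.bins["start"] >= locus["start"]
                    ) & (grid.bins["start"] < locus["end"])
                    est = float(np.mean(tracks[pop].cn[sel.to_numpy()]))
                    assert 5.5 <= est <= 6.5
                    found = True
        assert found

    def test_diploid_rmse_below_half_copy(self, cohort):
        """Per-bin CN RMSE over diploid sequence at 10x pooled coverage."""
        land, grid = cohort["landscape"], cohort["grid"]
        outside = ~grid.overlap_mask(land.loci)
        for pop, track in cohort["cn_tracks"].items():
            rmse = float(np.sqrt(np.mean((track.cn[outside] - 2.0) ** 2)))
            assert rmse <= 0.5
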