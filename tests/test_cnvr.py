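"""MCR chaining and CNVR ascertainment: the printed truth-table rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from suscape import cnvr
from suscape.depth import BinGrid, CNTrack


def _grid(n, bin_size=1000, drop=()):
    starts = [i * bin_size for i in range(n) if i not in drop]
    bins = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "unmasked": bin_size, "gc": 0.4}
    )
    return BinGrid(bins, bin_size)


class TestCallMCRs:
    def test_six_high_bins_form_one_mcr(self):
        grid = _grid(6)
        mcrs = cnvr.call_mcrs(CNTrack("p", np.full(6, 2.6)), grid)
        assert len(mcrs) == 1
        row = mcrs.iloc[0]
        assert (row["start"], row["end"], row["n_bins"]) == (0, 6000, 6)
        assert np.isclose(row["mean_cn"], 2.6)

    def test_five_high_bins_are_not_enough(self):
        grid = _grid(5)
        assert len(cnvr.call_mcrs(CNTrack("p", np.full(5, 2.6)), grid)) == 0

    def test_low_bin_splits_run_keeping_only_long_part(self):
        """[2.6 x2, 2.4, 2.6 x6]: only the trailing 6-bin run qualifies."""
        cn = np.array([2.6, 2.6, 2.4, 2.6, 2.6, 2.6, 2.6, 2.6, 2.6])
        mcrs = cnvr.call_mcrs(CNTrack("p", cn), _grid(9))
        assert len(mcrs) == 1
        assert (mcrs.iloc[0]["start"], mcrs.iloc[0]["end"]) == (3000, 9000)

    def test_dropped_bin_breaks_contiguity(self):
        """Seven high bins interrupted by a masked (dropped) bin leave two
        short runs, neither long enough."""
        grid = _grid(8, drop=(3,))
        mcrs = cnvr.call_mcrs(CNTrack("p", np.full(7, 3.0)), grid)
        assert len(mcrs) == 0

    def test_threshold_is_inclusive_at_2_5(self):
        mcrs = cnvr.call_mcrs(CNTrack("p", np.full(6, 2.5)), _grid(6))
        assert len(mcrs) == 1


class TestMergeMCRs:
    def test_partial_overlap_merges(self):
        a = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 20_000, "population": "A"}])
        b = pd.DataFrame([{"chrom": "chr1", "start": 18_000, "end": 30_000, "population": "B"}])
        merged = cnvr.merge_mcrs([a, b])
        assert len(merged) == 1
        assert (merged.iloc[0]["start"], merged.iloc[0]["end"]) == (10_000, 30_000)
        assert merged.iloc[0]["populations"] == "A,B"

    def test_disjoint_intervals_unchanged(self):
        a = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 6_000, "population": "A"}])
        b = pd.DataFrame([{"chrom": "chr1", "start": 6_000, "end": 12_000, "population": "B"}])
        assert len(cnvr.merge_mcrs([a, b])) == 2  # book-ended, no shared bp

    def test_transitive_chaining(self):
        a = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10_000, "population": "A"}])
        b = pd.DataFrame([{"chrom": "chr1", "start": 9_000, "end": 20_000, "population": "B"}])
        c = pd.DataFrame([{"chrom": "chr1", "start": 19_000, "end": 30_000, "population": "C"}])
        merged = cnvr.merge_mcrs([a, b, c])
        assert len(merged) == 1
        assert merged.iloc[0]["populations"] == "A,B,C"


class TestScoreAndAscertain:
    def test_region_mean_cn(self):
        grid = _grid(4)
        tracks = {"A": CNTrack("A", np.array([3.0, 5.0, 2.0, 2.0])), "B": CNTrack("B", np.full(4, 4.2))}
        regions = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 2000}])
        scored = cnvr.score_regions(regions, tracks, grid)
        assert np.isclose(scored.iloc[0]["A"], 4.0)
        assert np.isclose(scored.iloc[0]["B"], 4.2)

    def test_region_without_bins_is_an_error(self):
        grid = _grid(4)
        tracks = {"A": CNTrack("A", np.full(4, 2.0))}
        regions = pd.DataFrame([{"chrom": "chr1", "start": 50_000, "end": 60_000}])
        with pytest.raises(ValueError):
            cnvr.score_regions(regions, tracks, grid)

    @pytest.mark.parametrize(
        "vector,accepted",
        [
            ([3, 3, 3, 3, 3, 3, 3], False),  # s.d. 0
            ([2, 2, 2, 2, 2, 2, 4], True),  # s.d. ~0.756
            ([2, 2, 2, 2, 2, 2, 3], False),  # s.d. ~0.378
        ],
    )
    def test_sd_truth_table(self, vector, accepted):
        pops = [f"P{i}" for i in range(7)]
        scored = pd.DataFrame([dict(chrom="chr1", start=0, end=6000, **dict(zip(pops, vector)))])
        out = cnvr.ascertain_cnvrs(scored, pops)
        assert (len(out) == 1) == accepted
        if accepted:
            assert np.isclose(out.iloc[0]["sd"], np.std(vector, ddof=1))

    def test_sd_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        pops = [f"P{i}" for i in range(7)]
        scored = pd.DataFrame(rng.uniform(0, 8, size=(40, 7)), columns=pops)
        scored.insert(0, "chrom", "chr1")
        scored.insert(1, "start", np.arange(40) * 6000)
        scored.insert(2, "end", np.arange(1, 41) * 6000)
        sizes = [len(cnvr.ascertain_cnvrs(scored, pops, sd_threshold=s)) for s in (0.3, 0.7, 1.2, 2.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_ascertainment_permutation_invariant(self):
        pops = [f"P{i}" for i in range(7)]
        rng = np.random.default_rng(1)
        scored = pd.DataFrame(rng.uniform(0, 6, size=(30, 7)), columns=pops)
        scored.insert(0, "chrom", "chr1")
        scored.insert(1, "start", np.arange(30) * 6000)
        scored.insert(2, "end", np.arange(1, 31) * 6000)
        a = cnvr.ascertain_cnvrs(scored, pops)
        b = cnvr.ascertain_cnvrs(scored, pops[::-1])
        assert list(a.index) == list(b.index) and np.allclose(a["sd"], b["sd"])


class TestPopulationSpecific:
    @pytest.mark.parametrize(
        "vector,specific",
        [
            ([2, 2, 2, 2, 2, 2, 6], True),
            ([2, 2, 2, 2, 2, 4, 6], False),
            ([2.4, 2.4, 2.4, 2.4, 2.4, 2.4, 2.6], True),  # boundary of the 2.5 rule
        ],
    )
    def test_rule(self, vector, specific):
        pops = [f"P{i}" for i in range(7)]
        frame = pd.DataFrame([dict(chrom="chr1", start=0, end=6000, **dict(zip(pops, vector)))])
        assert (len(cnvr.population_specific(frame, pops)) == 1) == specific


class TestGroups:
    def test_identical_tracks_give_empty_unique_sets(self, cohort):
        tracks, grid = cohort["cn_tracks"], cohort["grid"]
        pops = list(tracks)
        a = cnvr.group_ascertain(tracks, grid, pops[:3])
        parts = cnvr.compare_groups(a, a.copy())
        assert len(parts["unique_a"]) == 0 and len(parts["unique_b"]) == 0
        assert len(parts["shared_a"]) == len(a)

    def test_group_smaller_than_two_rejected(self, cohort):
        with pytest.raises(ValueError):
            cnvr.group_ascertain(cohort["cn_tracks"], cohort["grid"], ["Sbar"])

    def test_resampling_three_of_four(self):
        combos = cnvr.resample_combinations(["a", "b", "c", "d"], 3)
        assert len(combos) == 4
        assert ["a", "b", "c"] in combos

    def test_group_unique_regions_recovered(self, cohort):
        """Regions variable only within one group surface as group-unique."""
        tracks, grid = cohort["cn_tracks"], cohort["grid"]
        land = cohort["landscape"]
        g1 = ["Sumatra", "China", "Europe"]
        g2 = ["Sbar", "Sceb", "Scel", "Sver"]
        set1 = cnvr.group_ascertain(tracks, grid, g1)
        set2 = cnvr.group_ascertain(tracks, grid, g2)
        parts = cnvr.compare_groups(set1, set2)
        idx = {p: land.populations.index(p) for p in land.populations}
        only_g1 = [
            i for i in range(len(land.loci))
            if np.std(land.cn[i, [idx[p] for p in g1]], ddof=1) >= 1.0
            and np.std(land.cn[i, [idx[p] for p in g2]], ddof=1) < 0.7
        ]
        if only_g1:
            loci = land.loci.iloc[only_g1]
            hit = 0
            for _, r in loci.iterrows():
                u = parts["unique_a"]
                if ((u["chrom"] == r["chrom"]) & (u["start"] < r["end"]) & (u["end"] > r["start"])).any():
                    hit += 1
            assert hit >= len(only_g1) * 0.8


@given(st.floats(min_value=0.0, max_value=3.0), st.integers(min_value=2, max_value=12))
def test_call_mcrs_never_returns_short_or_low_runs(threshold, min_bins):
    rng = np.random.default_rng(42)
    cn = rng.uniform(0, 5, 60)
    grid = _grid(60)
    mcrs = cnvr.call_mcrs(CNTrack("p", cn), grid, seed_threshold=threshold, min_bins=min_bins)
    for _, row in mcrs.iterrows():
        sel = (grid.bins["start"] >= row["start"]) & (grid.bins["start"] < row["end"])
        assert sel.sum() >= min_bins
        assert (cn[sel.to_numpy()] >= threshold).all()
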