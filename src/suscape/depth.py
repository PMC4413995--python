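"""From per-bin read depth to GC-corrected, diploid-calibrated copy number.

The read-depth (RD) method infers the copy number (CN) of a genomic window
from its mean sequencing depth relative to the depth of known-diploid
sequence.  The stages, each exposed separately and chained by
:func:`depth_to_cn`:

1. a bin grid over the repeat-masked genome (1 kb bins, retained only when
   >= 300 unmasked bases remain);
2. pooling the individuals of a population by summing raw depth;
3. multiplicative GC-stratum correction factors fitted on a reference bin
   set and applied to every bin;
4. two-stage diploid calibration: seed regions assumed diploid give a first
   mean diploid depth d2, bins with provisional CN in [1.5, 2.5) are then
   re-classified as diploid and d2 recomputed once from them;
5. CN per bin = 2 * corrected depth / d2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BinGrid:
    """Retained bins (sorted, non-overlapping) with unmasked-base and GC
    metadata.  `bins` has columns chrom, start, unmasked, gc."""

    bins: pd.DataFrame
    bin_size: int

    def __len__(self) -> int:
        return len(self.bins)

    def run_starts(self) -> np.ndarray:
        """Boolean per bin: True where a new run of consecutive retained
        bins begins (a dropped bin or chromosome change breaks a run)."""
        chrom = self.bins["chrom"].to_numpy()
        start = self.bins["start"].to_numpy()
        brk = np.ones(len(self.bins), dtype=bool)
        if len(self.bins) > 1:
            brk[1:] = (chrom[1:] != chrom[:-1]) | (start[1:] != start[:-1] + self.bin_size)
        return brk

    def overlap_mask(self, regions: pd.DataFrame) -> np.ndarray:
        """Boolean per retained bin: overlaps (>= 1 bp) any of `regions`
        (columns chrom, start, end)."""
        out = np.zeros(len(self.bins), dtype=bool)
        chrom = self.bins["chrom"].to_numpy()
        start = self.bins["start"].to_numpy()
        for c in np.unique(regions["chrom"]):
            sel = np.flatnonzero(chrom == c)
            if not len(sel):
                continue
            s = start[sel]
            for _, r in regions[regions["chrom"] == c].iterrows():
                lo = np.searchsorted(s, r["start"] - self.bin_size, side="right")
                hi = np.searchsorted(s, r["end"], side="left")
                out[sel[lo:hi]] = True
        return out


@dataclass
class DepthTrack:
    """Mean depth per retained bin (aligned with a BinGrid) for one
    population or individual."""

    population: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)


@dataclass
class GCModel:
    """Multiplicative per-GC-stratum depth correction factors."""

    edges: np.ndarray  # stratum boundaries partitioning [0, 1]
    factors: np.ndarray  # one factor per stratum, > 0 and finite
    min_bins: int  # strata with fewer reference bins inherit a neighbour

    def stratum(self, gc: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(self.edges, gc, side="right") - 1, 0, len(self.factors) - 1)

    def apply(self, depth: np.ndarray, gc: np.ndarray) -> np.ndarray:
        return depth * self.factors[self.stratum(gc)]


@dataclass
class DiploidCalibration:
    d2: float  # mean diploid depth after the single recalculation
    diploid_bins: np.ndarray  # boolean over grid bins (stage-2 diploid set)
    stage1_d2: float

    def __post_init__(self) -> None:
        if not self.d2 > 0:
            raise ValueError("mean diploid depth must be > 0")


@dataclass
class CNTrack:
    population: str
    cn: np.ndarray  # per retained bin, real, >= 0


# ---------------------------------------------------------------------------


def _union_intervals(intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    ivals = intervals[np.argsort(intervals[:, 0])]
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def build_bins(
    genome=None,
    *,
    mask: dict[str, np.ndarray] | None = None,
    chrom_sizes: dict[str, int] | None = None,
    gc: dict[str, np.ndarray] | None = None,
    bin_size: int = 1000,
    min_unmasked: int = 300,
    blacklist: tuple[str, ...] = (),
) -> BinGrid:
    """Build the retained-bin grid.

    Either pass a :class:`~suscape.simulate.SimulatedGenome`-like object
    (with bin_size, chrom_sizes, unmasked, gc) or raw `mask` intervals plus
    `chrom_sizes` (overlapping mask intervals are unioned).  Bins are kept
    only with >= `min_unmasked` unmasked bases; `blacklist` drops whole
    chromosomes (e.g. sex chromosomes).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if genome is not None:
        bin_size = genome.bin_size
        unmasked = genome.unmasked
        chrom_sizes = genome.chrom_sizes
        gc = genome.gc
    else:
        if chrom_sizes is None:
            raise ValueError("need a genome or chrom_sizes")
        mask = mask or {}
        unmasked = {}
        for chrom, size in chrom_sizes.items():
            n_bins = (size + bin_size - 1) // bin_size
            masked = np.zeros(n_bins, dtype=np.int64)
            for s, e in _union_intervals(np.asarray(mask.get(chrom, np.zeros((0, 2))), dtype=np.int64)):
                if s < 0 or e > size:
                    raise ValueError("mask interval outside chromosome bounds")
                b0, b1 = s // bin_size, (e - 1) // bin_size
                if b0 == b1:
                    masked[b0] += e - s
                else:
                    masked[b0] += (b0 + 1) * bin_size - s
                    masked[b1] += e - b1 * bin_size
                    masked[b0 + 1 : b1] += bin_size
            widths = np.full(n_bins, bin_size, dtype=np.int64)
            widths[-1] = size - (n_bins - 1) * bin_size
            unmasked[chrom] = widths - masked
    rows = []
    for chrom in chrom_sizes:
        if chrom in blacklist:
            continue
        unm = unmasked[chrom]
        keep = np.flatnonzero(unm >= min_unmasked)
        gc_track = gc[chrom] if gc is not None and chrom in gc else np.full(len(unm), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": keep * bin_size,
                    "unmasked": unm[keep],
                    "gc": np.asarray(gc_track)[keep],
                }
            )
        )
    bins = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["chrom", "start", "unmasked", "gc"])
    bins = bins.sort_values(["chrom", "start"]).reset_index(drop=True)
    return BinGrid(bins, bin_size)


def track_from_bins(grid: BinGrid, per_chrom_depth: dict[str, np.ndarray], label: str) -> DepthTrack:
    """Align a per-bin depth dict (as produced by the simulator) with the
    retained bins of `grid`."""
    chrom = grid.bins["chrom"].to_numpy()
    idx = grid.bins["start"].to_numpy() // grid.bin_size
    depth = np.empty(len(grid))
    for c in np.unique(chrom):
        sel = chrom == c
        depth[sel] = per_chrom_depth[c][idx[sel]]
    return DepthTrack(label, depth)


def pool_population(tracks: list[DepthTrack], population: str | None = None) -> DepthTrack:
    """Merge individuals of one population by summing per-bin depth."""
    if not tracks:
        raise ValueError("need at least one individual track")
    n = len(tracks[0].depth)
    if any(len(t.depth) != n for t in tracks):
        raise ValueError("tracks are on different bin grids")
    return DepthTrack(population or tracks[0].population, np.sum([t.depth for t in tracks], axis=0))


def fit_gc_model(
    track: DepthTrack,
    grid: BinGrid,
    reference: np.ndarray | None = None,
    stratum_width: float = 0.01,
    min_bins: int = 100,
) -> GCModel:
    """Per-GC-stratum correction factors from a reference bin set.

    factor(s) = mean reference depth / mean reference depth in stratum s;
    strata with fewer than `min_bins` reference bins inherit the nearest
    populated stratum's factor.  Factors are then rescaled so applying the
    model leaves the reference-set mean depth exactly unchanged.
    """
    if reference is None:
        reference = np.ones(len(grid), dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if not reference.any():
        raise ValueError("empty GC reference set")
    edges = np.arange(0.0, 1.0 + stratum_width / 2, stratum_width)
    n_strata = len(edges) - 1
    gc = grid.bins["gc"].to_numpy()
    depth = track.depth
    strata = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, n_strata - 1)
    global_mean = float(np.mean(depth[reference]))
    factors = np.full(n_strata, np.nan)
    counts = np.zeros(n_strata, dtype=np.int64)
    for s in range(n_strata):
        sel = reference & (strata == s)
        counts[s] = sel.sum()
        if counts[s] >= min_bins:
            m = float(np.mean(depth[sel]))
            if m > 0:
                factors[s] = global_mean / m
    populated = np.flatnonzero(np.isfinite(factors))
    if not len(populated):
        # reference too sparse to stratify: leave depth uncorrected rather
        # than amplify noise from a handful of bins per stratum
        warnings.warn("no GC stratum reaches min_bins reference bins; factors set to 1")
        factors[:] = 1.0
    else:
        for s in np.flatnonzero(~np.isfinite(factors)):
            factors[s] = factors[populated[np.argmin(np.abs(populated - s))]]
    model = GCModel(edges, factors, min_bins)
    corrected_mean = float(np.mean(model.apply(depth, gc)[reference]))
    model.factors = factors * (global_mean / corrected_mean)
    return model


def fit_and_apply_gc_correction(
    track: DepthTrack,
    grid: BinGrid,
    reference: np.ndarray | None = None,
    **kwargs,
) -> tuple[GCModel, DepthTrack]:
    model = fit_gc_model(track, grid, reference, **kwargs)
    corrected = model.apply(track.depth, grid.bins["gc"].to_numpy())
    return model, DepthTrack(track.population, corrected)


def calibrate_diploid(
    corrected: DepthTrack,
    grid: BinGrid,
    seed_regions: pd.DataFrame,
    diploid_window: tuple[float, float] = (1.5, 2.5),
    min_seed_bins: int = 50,
) -> DiploidCalibration:
    """Two-stage diploid depth calibration.

    Stage 1 averages depth over bins overlapping the assumed-diploid seed
    regions; stage 2 re-classifies every bin with provisional CN in
    `diploid_window` (closed on the left, open on the right) as diploid and
    recomputes the mean once.  Stage 2 washes out non-diploid contamination
    of the seed set and any GC skew of genic seed regions.
    """
    seed_mask = grid.overlap_mask(seed_regions)
    if seed_mask.sum() < min_seed_bins:
        raise ValueError(f"seed regions cover {seed_mask.sum()} bins < {min_seed_bins}")
    stage1 = float(np.mean(corrected.depth[seed_mask]))
    if not stage1 > 0:
        raise ValueError("stage-1 diploid depth is not positive")
    provisional = 2.0 * corrected.depth / stage1
    diploid = (provisional >= diploid_window[0]) & (provisional < diploid_window[1])
    if not diploid.any():
        raise ValueError("stage-2 diploid bin set is empty")
    d2 = float(np.mean(corrected.depth[diploid]))
    return DiploidCalibration(d2, diploid, stage1)


def estimate_cn(corrected: DepthTrack, calibration: DiploidCalibration) -> CNTrack:
    """CN per bin = 2 * corrected depth / mean diploid depth."""
    return CNTrack(corrected.population, 2.0 * corrected.depth / calibration.d2)


@dataclass
class CNResult:
    cn: CNTrack
    corrected: DepthTrack
    gc_model: GCModel
    calibration: DiploidCalibration


def depth_to_cn(
    individual_tracks: list[DepthTrack],
    grid: BinGrid,
    seed_regions: pd.DataFrame,
    population: str | None = None,
    gc_reference: str = "diploid",
    **gc_kwargs,
) -> CNResult:
    """Pooled depth -> CN for one population.

    `gc_reference` picks the bin set the GC factors are fitted on:
    "seed" (seed-region bins), "all" (every retained bin) or "diploid"
    (default): fit on seed bins, calibrate, then refit on the stage-2
    diploid set and recalibrate, so the factors come from genome-wide
    diploid sequence rather than genic seed regions only.
    """
    pooled = pool_population(individual_tracks, population)
    seed_mask = grid.overlap_mask(seed_regions)
    if gc_reference == "all":
        reference = np.ones(len(grid), dtype=bool)
    elif gc_reference in ("seed", "diploid"):
        reference = seed_mask
    else:
        raise ValueError(f"unknown gc_reference {gc_reference!r}")
    model, corrected = fit_and_apply_gc_correction(pooled, grid, reference, **gc_kwargs)
    calibration = calibrate_diploid(corrected, grid, seed_regions)
    if gc_reference == "diploid":
        model, corrected = fit_and_apply_gc_correction(pooled, grid, calibration.diploid_bins, **gc_kwargs)
        d2 = float(np.mean(corrected.depth[calibration.diploid_bins]))
        calibration = DiploidCalibration(d2, calibration.diploid_bins, calibration.stage1_d2)
    return CNResult(estimate_cn(corrected, calibration), corrected, model, calibration)
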