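"""Multi-copy regions (MCRs) and copy-number variable regions (CNVRs).

Per population, bins with CN >= 2.5 are chained into MCRs; runs shorter
than 6 bins are discarded, and a dropped (masked) bin breaks a run.  MCRs
from all populations are merged by single-linkage overlap, each merged
region is re-scored in every population (mean CN over its retained bins),
and regions whose per-population CN has sample standard deviation >= 0.7
are ascertained as CNVRs.  Group-restricted ascertainment re-runs the whole
chain within a subset of populations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .depth import BinGrid, CNTrack

SEED_CN = 2.5
MIN_BINS = 6
SD_THRESHOLD = 0.7


def call_mcrs(
    cn: CNTrack,
    grid: BinGrid,
    seed_threshold: float = SEED_CN,
    min_bins: int = MIN_BINS,
) -> pd.DataFrame:
    """Maximal runs of >= `min_bins` consecutive retained bins with
    CN >= `seed_threshold` for one population."""
    values = np.asarray(cn.cn, dtype=float)
    ok = np.nan_to_num(values, nan=-np.inf) >= seed_threshold
    breaks = grid.run_starts()
    prev_ok = np.concatenate(([False], ok[:-1]))
    next_ok = np.concatenate((ok[1:], [False]))
    next_breaks = np.concatenate((breaks[1:], [True]))
    starts = np.flatnonzero(ok & (~prev_ok | breaks))
    ends = np.flatnonzero(ok & (~next_ok | next_breaks))
    chrom = grid.bins["chrom"].to_numpy()
    start = grid.bins["start"].to_numpy()
    rows = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n < min_bins:
            continue
        rows.append(
            {
                "chrom": chrom[s],
                "start": int(start[s]),
                "end": int(start[e] + grid.bin_size),
                "population": cn.population,
                "mean_cn": float(np.mean(values[s : e + 1])),
                "n_bins": int(n),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "population", "mean_cn", "n_bins"])


def merge_mcrs(mcr_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Single-linkage union of per-population MCRs: intervals sharing >= 1 bp
    merge transitively; each merged region records its contributing
    populations."""
    allm = pd.concat([f for f in mcr_frames if len(f)], ignore_index=True) if any(len(f) for f in mcr_frames) else pd.DataFrame(columns=["chrom", "start", "end", "population"])
    rows = []
    for chrom, sub in allm.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        pops: set[str] = set()
        for _, r in sub.iterrows():
            if cur_s is None:
                cur_s, cur_e, pops = r["start"], r["end"], {r["population"]}
            elif r["start"] < cur_e:  # strict: sharing >= 1 bp
                cur_e = max(cur_e, r["end"])
                pops.add(r["population"])
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e), "populations": ",".join(sorted(pops))})
                cur_s, cur_e, pops = r["start"], r["end"], {r["population"]}
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e), "populations": ",".join(sorted(pops))})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "populations"])


def score_regions(
    regions: pd.DataFrame,
    cn_tracks: dict[str, CNTrack],
    grid: BinGrid,
) -> pd.DataFrame:
    """Mean CN of every region in every population.

    Returns `regions` with one CN column per population plus a `missing`
    column listing populations with no scorable bin (their CN is recorded
    as 0 so vectors stay rectangular).  A region with no retained bin at
    all is an error.
    """
    chrom = grid.bins["chrom"].to_numpy()
    start = grid.bins["start"].to_numpy()
    out = regions.reset_index(drop=True).copy()
    pops = list(cn_tracks)
    values = {p: np.asarray(cn_tracks[p].cn, dtype=float) for p in pops}
    scored = {p: np.zeros(len(out)) for p in pops}
    missing = [[] for _ in range(len(out))]
    for c in out["chrom"].unique():
        sel = np.flatnonzero(chrom == c)
        s = start[sel]
        for i in out.index[out["chrom"] == c]:
            lo = np.searchsorted(s, out.at[i, "start"] - grid.bin_size, side="right")
            hi = np.searchsorted(s, out.at[i, "end"], side="left")
            idx = sel[lo:hi]
            if len(idx) == 0:
                raise ValueError(f"region {c}:{out.at[i, 'start']}-{out.at[i, 'end']} has no retained bin")
            for p in pops:
                v = values[p][idx]
                finite = np.isfinite(v)
                if finite.any():
                    scored[p][i] = float(np.mean(v[finite]))
                else:
                    scored[p][i] = 0.0
                    missing[i].append(p)
    for p in pops:
        out[p] = scored[p]
    out["missing"] = [",".join(m) for m in missing]
    return out


def ascertain_cnvrs(
    scored: pd.DataFrame,
    populations: list[str],
    sd_threshold: float = SD_THRESHOLD,
) -> pd.DataFrame:
    """Keep regions whose per-population CN vector has sample (n-1)
    standard deviation >= `sd_threshold`."""
    if len(populations) < 2:
        raise ValueError("need >= 2 populations to ascertain CNVRs")
    cn = scored[list(populations)].to_numpy(dtype=float)
    sd = np.std(cn, axis=1, ddof=1)
    out = scored.copy()
    out["sd"] = sd
    return out[out["sd"] >= sd_threshold].reset_index(drop=True)


def population_specific(
    cnvrs: pd.DataFrame,
    populations: list[str],
    threshold: float = SEED_CN,
) -> pd.DataFrame:
    """CNVRs with CN >= `threshold` in exactly one population and below it
    in all others."""
    cn = cnvrs[list(populations)].to_numpy(dtype=float)
    hits = (cn >= threshold).sum(axis=1)
    return cnvrs[hits == 1].reset_index(drop=True)


def cnvr_pipeline(
    cn_tracks: dict[str, CNTrack],
    grid: BinGrid,
    seed_threshold: float = SEED_CN,
    min_bins: int = MIN_BINS,
    sd_threshold: float = SD_THRESHOLD,
) -> dict:
    """MCR calling -> merging -> scoring -> ascertainment for a set of
    population CN tracks; returns all intermediates."""
    mcrs = {p: call_mcrs(t, grid, seed_threshold, min_bins) for p, t in cn_tracks.items()}
    merged = merge_mcrs(list(mcrs.values()))
    if len(merged):
        scored = score_regions(merged, cn_tracks, grid)
        cnvrs = ascertain_cnvrs(scored, list(cn_tracks), sd_threshold)
    else:
        scored = merged.assign(**{p: [] for p in cn_tracks})
        cnvrs = scored.assign(sd=[])
    return {"mcrs": mcrs, "merged": merged, "scored": scored, "cnvrs": cnvrs}


def group_ascertain(
    cn_tracks: dict[str, CNTrack],
    grid: BinGrid,
    group: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Re-run the full MCR -> CNVR chain using only the populations of one
    group (e.g. the *Sus scrofa* vs island-species split)."""
    if len(group) < 2:
        raise ValueError("a group needs >= 2 populations")
    subset = {p: cn_tracks[p] for p in group}
    return cnvr_pipeline(subset, grid, **kwargs)["cnvrs"]


def _overlaps_any(region, others: pd.DataFrame) -> bool:
    same = others[others["chrom"] == region["chrom"]]
    return bool(((same["start"] < region["end"]) & (same["end"] > region["start"])).any())


def compare_groups(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition two group-ascertained CNVR sets into shared (>= 1 bp
    overlap with the other group's set) and group-unique regions."""
    shared_a = set_a[[_overlaps_any(r, set_b) for _, r in set_a.iterrows()]].reset_index(drop=True)
    unique_a = set_a[[not _overlaps_any(r, set_b) for _, r in set_a.iterrows()]].reset_index(drop=True)
    shared_b = set_b[[_overlaps_any(r, set_a) for _, r in set_b.iterrows()]].reset_index(drop=True)
    unique_b = set_b[[not _overlaps_any(r, set_a) for _, r in set_b.iterrows()]].reset_index(drop=True)
    return {"shared_a": shared_a, "unique_a": unique_a, "shared_b": shared_b, "unique_b": unique_b}


def resample_combinations(populations: list[str], size: int) -> list[list[str]]:
    """All `size`-population subsets, for leave-one-out style robustness
    checks of group ascertainment."""
    return [list(c) for c in combinations(populations, size)]
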