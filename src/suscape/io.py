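"""Readers and writers for the pipeline's on-disk formats.

All genomic intervals are 0-based half-open (BED convention) on disk and in
memory.  Interval readers tolerate unsorted input and sort internally.
Depth input is a 3-column TSV (chrom, position-or-bin-start, depth), either
one row per bin or one row per base (binned on the fly).  Distance matrices
go out as relaxed-label square PHYLIP; discretised characters as NEXUS
standard-datatype; trees as Newick.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trees import Tree

# --------------------------------------------------------------------- BED


def read_bed(path, names: tuple[str, ...] = ("chrom", "start", "end", "name", "cls")) -> pd.DataFrame:
    """Read a BED-like TSV (3+ columns), sort by position."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names[: df.shape[1]])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: BED intervals must have end > start")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in df.columns]
    df = df.sort_values(["chrom", "start"])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def mask_to_bed(mask: dict[str, np.ndarray], path) -> None:
    rows = [(chrom, int(s), int(e)) for chrom, ivals in mask.items() for s, e in ivals]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(path, sep="\t", header=False, index=False)


def bed_to_mask(path) -> dict[str, np.ndarray]:
    df = read_bed(path, names=("chrom", "start", "end"))
    return {c: sub[["start", "end"]].to_numpy(np.int64) for c, sub in df.groupby("chrom")}


# ------------------------------------------------------------------- depth


def write_depth_tsv(per_chrom_depth: dict[str, np.ndarray], bin_size: int, path) -> None:
    """One row per bin: chrom, bin start (0-based), mean depth.  Fully
    masked bins (NaN depth) are omitted."""
    frames = []
    for chrom, depth in per_chrom_depth.items():
        ok = np.isfinite(depth)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": np.flatnonzero(ok) * bin_size, "depth": depth[ok]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_depth_tsv(
    path,
    chrom_sizes: dict[str, int],
    bin_size: int = 1000,
    per_base: bool = False,
) -> dict[str, np.ndarray]:
    """Read a 3-column depth TSV into per-chromosome per-bin arrays.

    `per_base=True` treats rows as (chrom, position, depth) samtools-depth
    style (positions may be 1-based or 0-based; binning by integer division
    is insensitive to that at 1 kb scale) and averages depth per bin over
    the rows present.  Missing bins get NaN.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"], comment="#")
    out = {}
    for chrom, size in chrom_sizes.items():
        n_bins = (size + bin_size - 1) // bin_size
        track = np.full(n_bins, np.nan)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            if per_base:
                bins = sub["pos"].to_numpy(np.int64) // bin_size
                sums = np.bincount(bins, weights=sub["depth"], minlength=n_bins)
                counts = np.bincount(bins, minlength=n_bins)
                with np.errstate(invalid="ignore"):
                    track = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            else:
                idx = sub["pos"].to_numpy(np.int64) // bin_size
                track[idx] = sub["depth"].to_numpy(float)
        out[chrom] = track
    return out


def write_cn_track(grid_bins: pd.DataFrame, cn: np.ndarray, bin_size: int, path) -> None:
    out = grid_bins[["chrom", "start"]].copy()
    out["end"] = out["start"] + bin_size
    out["cn"] = cn
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


# ------------------------------------------------------------- matrices


def write_cn_matrix(scored: pd.DataFrame, populations: list[str], path) -> None:
    """Regions x populations CN matrix TSV with region coordinates."""
    scored[["chrom", "start", "end", *populations]].to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_cn_matrix(path) -> tuple[pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t")
    pops = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return df, pops


def write_genotypes_tsv(names: list[str], genotypes: np.ndarray, path) -> None:
    pd.DataFrame(genotypes.T, columns=names).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return list(df.columns), df.to_numpy(np.uint8).T


def write_phylip(labels: list[str], matrix: np.ndarray, path) -> None:
    """Relaxed square PHYLIP distance matrix (labels may exceed 10 chars)."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        width = max(len(x) for x in labels) + 2
        for name, row in zip(labels, np.asarray(matrix)):
            fh.write(name.ljust(width) + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return labels, np.asarray(rows)


# ---------------------------------------------------------------- NEXUS


def write_nexus(matrix, path) -> None:
    """Discretised characters as a NEXUS standard-datatype block
    (symbols 0..k-1, suitable for external Bayesian tools)."""
    symbols = "".join(str(i) for i in range(matrix.k))
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_loci};\n")
        fh.write(f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
        fh.write("  MATRIX\n")
        for i, taxon in enumerate(matrix.taxa):
            seq = "".join(str(s) for s in matrix.states[:, i])
            fh.write(f"    {taxon.ljust(width)}{seq}\n")
        fh.write("  ;\nEND;\n")


def read_nexus(path) -> tuple[list[str], np.ndarray]:
    taxa, seqs = [], []
    in_matrix = False
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if stripped.startswith(";"):
                break
            if stripped:
                name, seq = stripped.split(None, 1)
                taxa.append(name)
                seqs.append([int(ch) for ch in seq.strip()])
    return taxa, np.asarray(seqs, dtype=np.int64).T


# ---------------------------------------------------------------- trees


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path) -> Tree:
    return Tree.from_newick(Path(path).read_text().strip())


def write_tree_samples(newicks: list[str], path) -> None:
    Path(path).write_text("\n".join(newicks) + "\n")


# ------------------------------------------------------------- manifests


def write_manifest(path, **entries) -> None:
    """Run manifest: every seed, parameter and per-stage row count, as JSON
    so reruns are byte-comparable."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
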