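"""Gene annotation of CNVRs and OR / non-OR partitioning.

A gene is considered copy-number variable when at least 70% of its length
overlaps the union of ascertained CNVRs; it inherits the per-population CN
of the single CNVR it overlaps most.  CNVR sets are then partitioned into
CNVR-OR (overlapping >= 1 olfactory-receptor gene), CNVR-nonOR
(overlapping >= 1 gene, none of them OR) and CNVR-ALL (everything); mixed
regions go to CNVR-OR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_OVERLAP_FRACTION = 0.70


def _merged_intervals(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, sub in frame.groupby("chrom"):
        ivals = sub[["start", "end"]].to_numpy()
        ivals = ivals[np.argsort(ivals[:, 0])]
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged)
    return out


def overlap_genes(
    cnvrs: pd.DataFrame,
    genes: pd.DataFrame,
    populations: list[str],
    min_frac: float = MIN_OVERLAP_FRACTION,
) -> pd.DataFrame:
    """Gene-CN table: genes whose overlap with the union of CNVRs is
    >= `min_frac` of the gene length.

    `genes` needs columns chrom, start, end, name, cls (OR | nonOR).  Each
    qualifying gene is assigned the per-population CN of the CNVR with the
    largest single overlap and that CNVR's row index (`cnvr_id`).
    """
    union = _merged_intervals(cnvrs) if len(cnvrs) else {}
    rows = []
    for _, g in genes.iterrows():
        length = g["end"] - g["start"]
        if length <= 0 or g["chrom"] not in union:
            continue
        ivals = union[g["chrom"]]
        ov = np.clip(np.minimum(ivals[:, 1], g["end"]) - np.maximum(ivals[:, 0], g["start"]), 0, None)
        total = int(ov.sum())
        if total < min_frac * length:
            continue
        same = cnvrs[cnvrs["chrom"] == g["chrom"]]
        per_cnvr = np.clip(
            np.minimum(same["end"].to_numpy(), g["end"]) - np.maximum(same["start"].to_numpy(), g["start"]),
            0,
            None,
        )
        best = same.index[int(np.argmax(per_cnvr))]
        row = {
            "gene": g["name"],
            "chrom": g["chrom"],
            "start": int(g["start"]),
            "end": int(g["end"]),
            "cls": g["cls"],
            "cnvr_id": best,
            "overlap_frac": total / length,
        }
        for p in populations:
            row[p] = cnvrs.at[best, p]
        rows.append(row)
    cols = ["gene", "chrom", "start", "end", "cls", "cnvr_id", "overlap_frac", *populations]
    return pd.DataFrame(rows, columns=cols)


def partition_by_class(cnvrs: pd.DataFrame, gene_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """{CNVR-OR, CNVR-nonOR, CNVR-ALL} partitions of a CNVR set.

    OR takes precedence: a CNVR overlapping both OR and non-OR genes is
    CNVR-OR, keeping OR and nonOR disjoint.
    """
    or_ids = set(gene_table.loc[gene_table["cls"] == "OR", "cnvr_id"])
    genic_ids = set(gene_table["cnvr_id"])
    non_or_ids = genic_ids - or_ids
    return {
        "OR": cnvrs.loc[sorted(or_ids & set(cnvrs.index))],
        "nonOR": cnvrs.loc[sorted(non_or_ids & set(cnvrs.index))],
        "ALL": cnvrs,
    }
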