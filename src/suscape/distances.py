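"""Pairwise copy-number-difference (CND) and SNP rates, and trees from them.

The CND between two samples at a locus is |CN_a - CN_b|, binarised at >= 2
(a jump from two to ten copies counts once, making the CND rate deliberately
conservative).  Rates divide difference counts by the locus / callable-site
total, giving values in [0, 1] comparable between the CND and SNP scales;
their ratio measures how much faster copy number evolves than single
nucleotides.  Trees: an exact Saitou-Nei neighbour joining (reproduces any
additive matrix), and agglomerative hierarchical clustering of CN vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .trees import Node, Tree


@dataclass
class RateMatrix:
    """Symmetric pairwise rates in [0, 1] with the denominator used."""

    labels: list[str]
    rates: np.ndarray
    denominator: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (len(self.labels), len(self.labels)):
            raise ValueError("rate matrix shape does not match labels")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 0):
            raise ValueError("rates must be symmetric with zero diagonal")
        self.rates = r


def binary_cnd(cn_matrix: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Pairwise counts of loci where |CN_a - CN_b| >= threshold.

    `cn_matrix` is loci x samples; the result is samples x samples.
    """
    cn = np.asarray(cn_matrix, dtype=float)
    n = cn.shape[1]
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            c = int(np.sum(np.abs(cn[:, i] - cn[:, j]) >= threshold))
            counts[i, j] = counts[j, i] = c
    return counts


def cnd_rate(counts: np.ndarray, n_loci: int, labels: list[str]) -> RateMatrix:
    if n_loci <= 0:
        raise ValueError("locus count must be > 0")
    return RateMatrix(list(labels), np.asarray(counts, dtype=float) / n_loci, n_loci)


def snp_rate(genotypes: np.ndarray, labels: list[str]) -> RateMatrix:
    """Pairwise difference fraction over callable sites
    (`genotypes` is samples x sites)."""
    g = np.asarray(genotypes)
    n, sites = g.shape
    if sites == 0:
        raise ValueError("no callable sites")
    rates = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rates[i, j] = rates[j, i] = np.mean(g[i] != g[j])
    return RateMatrix(list(labels), rates, sites)


def rate_ratio(cnd: RateMatrix, snp: RateMatrix) -> dict[str, float]:
    """Mean (plus min/max) over sample pairs of CND rate / SNP rate."""
    if cnd.labels != snp.labels:
        raise ValueError("rate matrices are over different samples")
    iu = np.triu_indices(len(cnd.labels), k=1)
    num, den = cnd.rates[iu], snp.rates[iu]
    if np.any(den == 0):
        raise ValueError("SNP rate is zero for some pair; ratio undefined")
    ratios = num / den
    return {"mean": float(np.mean(ratios)), "min": float(np.min(ratios)), "max": float(np.max(ratios))}


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(matrix: RateMatrix | np.ndarray, labels: list[str] | None = None) -> Tree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    The pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j is joined; ties
    are broken by the lexicographically smallest label pair (a cluster is
    labelled by its smallest leaf).  Negative branch lengths are clamped to
    0 with the deficit moved to the sibling branch, preserving the pair
    distance.  On an additive matrix the true topology and branch lengths
    are recovered exactly.
    """
    if isinstance(matrix, RateMatrix):
        labels = matrix.labels
        d = matrix.rates.copy().astype(float)
    else:
        d = np.asarray(matrix, dtype=float).copy()
        if labels is None:
            raise ValueError("labels required with a bare matrix")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list[Node] = [Node(name) for name in labels]
    keys: list[str] = list(labels)
    active = list(range(n))

    if n == 2:
        root = Node()
        for i in active:
            nodes[i].length = d[0, 1] / 2.0
            root.add(nodes[i])
        return Tree(root)

    while len(active) > 3:
        r = len(active)
        R = {i: float(sum(d[i, k] for k in active if k != i)) for i in active}
        best = None
        best_q = np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - R[i] - R[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and (best is None or pair_key < best[2])):
                    best, best_q = (i, j, pair_key), q
        i, j, _ = best
        bi = 0.5 * d[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        bj = d[i, j] - bi
        if bi < 0:
            bi, bj = 0.0, d[i, j]
        elif bj < 0:
            bi, bj = d[i, j], 0.0
        parent = Node()
        nodes[i].length, nodes[j].length = bi, bj
        parent.add(nodes[i])
        parent.add(nodes[j])
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    root = Node()
    for i, j, k in ((a, b, c), (b, a, c), (c, a, b)):
        nodes[i].length = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
        root.add(nodes[i])
    return Tree(root)


# ---------------------------------------------------------------------------
# hierarchical clustering


def hierarchical_cluster(
    cn_matrix: np.ndarray,
    labels: list[str],
    method: str = "complete",
) -> Tree:
    """Agglomerative clustering of per-sample CN vectors (loci x samples)
    into a rooted dendrogram with ultrametric branch lengths.

    Euclidean distances, complete linkage by default (the classic hclust
    default); `method` accepts any scipy linkage method.
    """
    x = np.asarray(cn_matrix, dtype=float).T
    if x.shape[0] != len(labels):
        raise ValueError("label count does not match samples")
    if len(labels) < 2:
        raise ValueError("need >= 2 samples")
    z = hierarchy.linkage(x, method=method, metric="euclidean")
    nodes = [Node(name) for name in labels]
    heights = [0.0] * len(labels)
    for i, j, h, _ in z:
        parent = Node()
        for child in (int(i), int(j)):
            nodes[child].length = h / 2.0 - heights[child] / 2.0
            parent.add(nodes[child])
        nodes.append(parent)
        heights.append(h)
    return Tree(nodes[-1])
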