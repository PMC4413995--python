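"""Mk / Mkv likelihood for discretised copy-number characters.

Copy numbers are rescaled per locus to k = 10 integer states,

    state = round((CN - CN_min) / (CN_max - CN_min) * (k - 1)),

rounding half away from zero, so the per-locus minimum maps to 0 and the
maximum to 9.  Characters evolve under the symmetric k-state Markov model
(all exchanges equally likely) with branch lengths in expected
substitutions per character:

    P_same(t) = 1/k + (k-1)/k * exp(-k t / (k-1))
    P_diff(t) = 1/k * (1 - exp(-k t / (k-1)))

Because only variable loci are observed (an invariant locus cannot be
rescaled), the likelihood is conditioned on variability (the "v" in Mkv):
each site likelihood is divided by one minus the summed probability of the
k all-constant patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trees import Tree


@dataclass
class CharacterMatrix:
    """Loci x taxa integer states in {0..k-1}, variable loci only."""

    taxa: list[str]
    states: np.ndarray
    k: int = 10
    locus_range: np.ndarray | None = None  # per-locus (raw CN min, max)

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int64)
        if s.ndim != 2 or s.shape[1] != len(self.taxa):
            raise ValueError("states must be loci x taxa")
        if s.size and (s.min() < 0 or s.max() >= self.k):
            raise ValueError(f"states must lie in 0..{self.k - 1}")
        if s.size and np.any(s.max(axis=1) == s.min(axis=1)):
            raise ValueError("constant loci are not allowed in a variable-only matrix")
        self.states = s

    @property
    def n_loci(self) -> int:
        return self.states.shape[0]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def discretize(cn_matrix: np.ndarray, taxa: list[str], k: int = 10) -> CharacterMatrix:
    """Rescale each locus's CN vector onto {0..k-1}.

    Loci with CN_max == CN_min carry no signal and are skipped with a
    warning.  The transform is invariant to per-locus affine rescaling.
    """
    cn = np.asarray(cn_matrix, dtype=float)
    mins = cn.min(axis=1)
    maxs = cn.max(axis=1)
    keep = maxs > mins
    if not keep.all():
        warnings.warn(f"skipping {int((~keep).sum())} invariant loci (CN_max == CN_min)")
    cn = cn[keep]
    mins, maxs = mins[keep], maxs[keep]
    scaled = (cn - mins[:, None]) / (maxs - mins)[:, None] * (k - 1)
    states = _round_half_away(scaled).astype(np.int64)
    return CharacterMatrix(list(taxa), states, k, np.column_stack([mins, maxs]))


def transition_probs(t: float, k: int) -> tuple[float, float]:
    """(P_same, P_diff) of the symmetric k-state chain at branch length t,
    normalised to one expected substitution per unit length."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = np.exp(-k * t / (k - 1))
    return 1.0 / k + (k - 1) / k * e, (1.0 - e) / k


def _pattern_partials(tree: Tree, patterns: np.ndarray, taxa: list[str], k: int) -> np.ndarray:
    """Uncorrected likelihood of each site pattern by postorder pruning
    with uniform root frequencies (patterns is n_pat x n_taxa)."""
    col = {name: i for i, name in enumerate(taxa)}
    n_pat = patterns.shape[0]
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in col:
                raise ValueError(f"taxon {node.name!r} missing from matrix")
            p = np.zeros((n_pat, k))
            p[np.arange(n_pat), patterns[:, col[node.name]]] = 1.0
            partial[id(node)] = p
            continue
        acc = np.ones((n_pat, k))
        for child in node.children:
            p_same, p_diff = transition_probs(child.length or 0.0, k)
            p = partial[id(child)]
            msg = p_diff * p.sum(axis=1, keepdims=True) + (p_same - p_diff) * p
            acc *= msg
            del partial[id(child)]
        partial[id(node)] = acc
    return partial[id(tree.root)].mean(axis=1)  # uniform 1/k root frequencies


def pattern_likelihoods(tree: Tree, matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(unique patterns, counts, uncorrected pattern likelihoods)."""
    patterns, counts = np.unique(matrix.states, axis=0, return_counts=True)
    lik = _pattern_partials(tree, patterns, matrix.taxa, matrix.k)
    return patterns, counts, lik


def constant_pattern_likelihoods(tree: Tree, taxa: list[str], k: int) -> np.ndarray:
    """Uncorrected likelihood of each of the k all-constant patterns."""
    const = np.repeat(np.arange(k)[:, None], len(taxa), axis=1)
    return _pattern_partials(tree, const, taxa, k)


def mkv_log_likelihood(tree: Tree, matrix: CharacterMatrix) -> float:
    """Variable-characters-conditioned log likelihood.

    L_v(site) = L(site) / (1 - sum_c L(all taxa constant at c)); returns
    -inf when a site pattern has zero probability (e.g. a variable site on
    an all-zero-length tree).
    """
    _, counts, lik = pattern_likelihoods(tree, matrix)
    p_const = float(constant_pattern_likelihoods(tree, matrix.taxa, matrix.k).sum())
    denom = 1.0 - p_const
    if denom <= 0 or np.any(~np.isfinite(lik)):
        return -np.inf
    with np.errstate(divide="ignore"):
        logs = np.log(lik) - np.log(denom)
    if np.any(np.isneginf(logs)):
        return -np.inf
    return float(np.dot(counts, logs))


# ---------------------------------------------------------------------------
# simulation under the model (for oracles and model-selection checks)


def simulate_mk(
    tree: Tree,
    n_loci: int,
    k: int = 10,
    seed: int = 0,
    variable_only: bool = True,
) -> CharacterMatrix:
    """Simulate characters on `tree` under the symmetric k-state model,
    optionally resampling until `n_loci` variable characters are obtained
    (matching the ascertainment the Mkv correction accounts for)."""
    rng = np.random.default_rng(seed)
    taxa = tree.leaf_names()
    out = np.empty((0, len(taxa)), dtype=np.int64)
    while out.shape[0] < n_loci:
        draw = max(n_loci - out.shape[0], 16)
        states = {id(tree.root): rng.integers(0, k, size=draw)}
        for node in tree.preorder():
            if node is tree.root:
                continue
            p_same, _ = transition_probs(node.length or 0.0, k)
            parent = states[id(node.parent)]
            stay = rng.random(draw) < p_same
            shift = rng.integers(1, k, size=draw)  # uniform over the other k-1
            states[id(node)] = np.where(stay, parent, (parent + shift) % k)
        block = np.column_stack([states[id(leaf)] for leaf in tree.leaves()])
        if variable_only:
            block = block[block.max(axis=1) != block.min(axis=1)]
        out = np.vstack([out, block])
    return CharacterMatrix(taxa, out[:n_loci], k)
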