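"""Bayesian phylogenetics on discretised copy-number characters.

Posterior sampling is plain Metropolis-Hastings over unrooted topologies
(symmetric NNI proposals, rejected when they break a constrained clade) and
branch lengths (multiplier proposals, Exponential(10) prior), with the Mkv
likelihood conditioned on variable characters.  Marginal likelihoods are
estimated by stepping-stone sampling along a Beta(0.3, 1)-quantile ladder
of power posteriors, and competing topology constraints are ranked by
delta-lnL = best marginal log likelihood minus each model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mkv import CharacterMatrix, _pattern_partials
from .trees import Tree, internal_edges, random_tree, unroot

BL_PRIOR_RATE = 10.0  # Exponential prior rate on branch lengths (mean 0.1)


@dataclass
class TopologyConstraint:
    """Named clades that must stay monophyletic (unrooted sense)."""

    name: str
    clades: list[frozenset[str]]

    def satisfied_by(self, tree: Tree) -> bool:
        return all(tree.has_clade(c) for c in self.clades)


def predefined_models(
    scrofa: tuple[str, ...] = ("Sumatra", "China", "Europe"),
    isea: tuple[str, ...] = ("Sbar", "Sceb", "Scel", "Sver"),
) -> dict[str, TopologyConstraint]:
    """The five admixture-scenario models: a null constraining the two major
    clades, and four two-taxon constraints representing known or suspected
    hybridisation/translocation pairs."""
    return {
        "null": TopologyConstraint("null", [frozenset(scrofa)]),
        "m1": TopologyConstraint("m1", [frozenset({"Sver", "Sumatra"})]),
        "m2": TopologyConstraint("m2", [frozenset({"Scel", "Sumatra"})]),
        "m3": TopologyConstraint("m3", [frozenset({"Sbar", "Sumatra"})]),
        "m4": TopologyConstraint("m4", [frozenset({"Sceb", "China"})]),
    }


# ---------------------------------------------------------------------------
# Markov chain


class _Chain:
    """MH kernel over (topology, branch lengths) targeting
    prior x likelihood^beta."""

    def __init__(
        self,
        matrix: CharacterMatrix | None,
        taxa: list[str],
        constraints: list[TopologyConstraint],
        rng: np.random.Generator,
        bl_prior_rate: float = BL_PRIOR_RATE,
        p_topology: float = 0.3,
        multiplier_scale: float = 1.0,
    ):
        self.matrix = matrix
        self.taxa = list(taxa)
        self.constraints = constraints
        self.rng = rng
        self.bl_rate = bl_prior_rate
        self.p_topology = p_topology
        self.mult = multiplier_scale
        clades = [c for con in constraints for c in con.clades]
        self.tree = unroot(random_tree(self.taxa, rng, clades))
        for node in self.tree.edges():
            node.length = float(rng.exponential(1.0 / bl_prior_rate))
        if matrix is not None:
            patterns, self._counts = np.unique(matrix.states, axis=0, return_counts=True)
            const = np.repeat(np.arange(matrix.k)[:, None], len(matrix.taxa), axis=1)
            # one pruning pass scores data patterns and the k constant
            # patterns of the ascertainment correction together
            self._patterns = np.vstack([patterns, const])
            self._n_data = len(patterns)
        self.log_lik = self._compute_log_lik()
        self.accepted = {"topology": 0, "length": 0}
        self.proposed = {"topology": 0, "length": 0}

    def _compute_log_lik(self) -> float:
        if self.matrix is None:
            return 0.0
        lik = _pattern_partials(self.tree, self._patterns, self.matrix.taxa, self.matrix.k)
        data_lik, const_lik = lik[: self._n_data], lik[self._n_data :]
        denom = 1.0 - float(const_lik.sum())
        if denom <= 0 or np.any(data_lik <= 0):
            return -np.inf
        return float(np.dot(self._counts, np.log(data_lik))) - len(self.matrix.states) * np.log(denom)

    @staticmethod
    def _exchange(parent, edge_child, a, b) -> None:
        """Swap subtree `a` (child of parent) with `b` (child of edge_child)."""
        pi = parent.children.index(a)
        ci = edge_child.children.index(b)
        parent.children[pi] = b
        b.parent = parent
        edge_child.children[ci] = a
        a.parent = edge_child

    def step(self, beta: float) -> None:
        rng = self.rng
        internal = internal_edges(self.tree)
        if internal and rng.random() < self.p_topology:
            self.proposed["topology"] += 1
            edge_child = internal[int(rng.integers(len(internal)))]
            parent = edge_child.parent
            siblings = [c for c in parent.children if c is not edge_child]
            sib = siblings[int(rng.integers(len(siblings)))]
            child = edge_child.children[int(rng.integers(len(edge_child.children)))]
            self._exchange(parent, edge_child, sib, child)
            if not all(con.satisfied_by(self.tree) for con in self.constraints):
                self._exchange(parent, edge_child, child, sib)
                return
            new_ll = self._compute_log_lik()
            if np.log(rng.random()) < beta * (new_ll - self.log_lik):
                self.log_lik = new_ll
                self.accepted["topology"] += 1
            else:
                self._exchange(parent, edge_child, child, sib)
        else:
            self.proposed["length"] += 1
            edges = self.tree.edges()
            node = edges[int(rng.integers(len(edges)))]
            old = node.length or 0.0
            m = float(np.exp(self.mult * (rng.random() - 0.5)))
            node.length = old * m if old > 0 else float(rng.exponential(1.0 / self.bl_rate))
            new_ll = self._compute_log_lik()
            log_alpha = (
                beta * (new_ll - self.log_lik)
                - self.bl_rate * (node.length - old)
                + (np.log(m) if old > 0 else 0.0)
            )
            if np.log(rng.random()) < log_alpha:
                self.log_lik = new_ll
                self.accepted["length"] += 1
            else:
                node.length = old


@dataclass
class McmcResult:
    trees: list[str]  # sampled newick strings (post burn-in, thinned)
    log_likelihoods: np.ndarray
    mean_branch_lengths: np.ndarray  # per sample, mean over branches
    acceptance: dict[str, float]

    def clade_support(self, clade: frozenset[str]) -> float:
        hits = sum(Tree.from_newick(t).has_clade(clade) for t in self.trees)
        return hits / len(self.trees)


def mcmc(
    matrix: CharacterMatrix | None,
    constraints: list[TopologyConstraint] | None = None,
    n_iter: int = 100_000,
    burnin: float = 0.25,
    thin: int = 20,
    seed: int = 0,
    taxa: list[str] | None = None,
    **chain_kwargs,
) -> McmcResult:
    """Posterior sampling of topology and branch lengths.

    `matrix=None` runs the likelihood-free chain (posterior = prior), which
    is the standard validation that proposals and priors are implemented
    consistently.  Sampled trees satisfy every constraint by construction
    (violating NNI proposals are rejected outright).
    """
    rng = np.random.default_rng(seed)
    taxa = taxa or (matrix.taxa if matrix is not None else None)
    if taxa is None:
        raise ValueError("need a matrix or an explicit taxon list")
    chain = _Chain(matrix, taxa, constraints or [], rng, **chain_kwargs)
    keep_from = int(n_iter * burnin)
    trees, lls, mbls = [], [], []
    for it in range(n_iter):
        chain.step(1.0)
        if it >= keep_from and (it - keep_from) % thin == 0:
            trees.append(chain.tree.to_newick())
            lls.append(chain.log_lik)
            mbls.append(np.mean([n.length or 0.0 for n in chain.tree.edges()]))
    acc = {
        k: chain.accepted[k] / chain.proposed[k] if chain.proposed[k] else np.nan
        for k in chain.accepted
    }
    return McmcResult(trees, np.asarray(lls), np.asarray(mbls), acc)


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


def power_betas(steps: int, alpha: float = 0.3) -> np.ndarray:
    """Ladder of inverse temperatures from quantiles of Beta(alpha, 1):
    beta_j = (j / steps)^(1/alpha), j = 0..steps; endpoints exactly 0, 1."""
    if steps < 2:
        raise ValueError("need >= 2 steps")
    return (np.arange(steps + 1) / steps) ** (1.0 / alpha)


@dataclass
class MarginalLikelihoodEstimate:
    model: str
    log_marginal: float
    steps: int
    per_step: np.ndarray = field(repr=False)
    mc_se: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_marginal):
            raise ValueError("marginal likelihood estimate is not finite")


def _stepping_stone_core(
    step_fn, loglik_fn, betas, samples_per_step, burnin, thin: int = 1
) -> tuple[float, np.ndarray, float]:
    """Shared ladder logic: `step_fn(beta)` advances the chain one MH step,
    `loglik_fn()` reports the current log likelihood.  Runs from the
    posterior end of the ladder towards the prior, reusing the chain state;
    `thin` MH steps separate recorded samples (single-branch updates mix
    slowly, so unthinned samples are strongly autocorrelated)."""
    contributions = np.empty(len(betas) - 1)
    variances = np.empty(len(betas) - 1)
    n_burn = int(samples_per_step * burnin)
    for j in range(len(betas) - 2, -1, -1):
        beta = betas[j]
        d_beta = betas[j + 1] - betas[j]
        lls = np.empty(samples_per_step)
        for i in range(n_burn * thin):
            step_fn(beta)
        for i in range(samples_per_step):
            for _ in range(thin):
                step_fn(beta)
            lls[i] = loglik_fn()
        contributions[j] = logsumexp(d_beta * lls) - np.log(samples_per_step)
        # batch-means variance: robust to residual autocorrelation
        n_batch = max(4, min(20, samples_per_step // 25))
        usable = (samples_per_step // n_batch) * n_batch
        batches = (d_beta * lls[:usable]).reshape(n_batch, -1)
        per_batch = logsumexp(batches, axis=1) - np.log(batches.shape[1])
        variances[j] = float(np.var(per_batch, ddof=1)) / n_batch
    return float(contributions.sum()), contributions, float(np.sqrt(variances.sum()))


def stepping_stone(
    matrix: CharacterMatrix,
    constraints: list[TopologyConstraint] | None = None,
    steps: int = 50,
    samples_per_step: int = 2_000,
    burnin: float = 0.25,
    alpha: float = 0.3,
    thin: int = 1,
    seed: int = 0,
    model_name: str = "model",
    **chain_kwargs,
) -> MarginalLikelihoodEstimate:
    """Stepping-stone estimate of ln p(data | constraint model).

    ln m = sum_j ln[(1/n) sum_i L(theta_i)^(beta_{j+1} - beta_j)] with
    theta_i drawn from the beta_j power posterior; the ladder follows
    Beta(alpha, 1) quantiles so steps crowd near the prior, where the
    integrand varies fastest.
    """
    rng = np.random.default_rng(seed)
    chain = _Chain(matrix, matrix.taxa, constraints or [], rng, **chain_kwargs)
    betas = power_betas(steps, alpha)
    lnm, per_step, se = _stepping_stone_core(
        chain.step, lambda: chain.log_lik, betas, samples_per_step, burnin, thin
    )
    return MarginalLikelihoodEstimate(model_name, lnm, steps, per_step, se)


def stepping_stone_generic(
    log_likelihood,
    propose,
    initial_state,
    steps: int = 50,
    samples_per_step: int = 2_000,
    burnin: float = 0.25,
    alpha: float = 0.3,
    thin: int = 1,
    seed: int = 0,
) -> MarginalLikelihoodEstimate:
    """Stepping stone for an arbitrary single-state model.

    `propose(state, rng) -> (new_state, log_extra)` where `log_extra` is the
    log Hastings ratio plus log prior ratio; sampling at beta=0 then targets
    the prior exactly.  Used for closed-form validation models.
    """
    rng = np.random.default_rng(seed)
    state = initial_state
    ll = log_likelihood(state)

    def step(beta: float) -> None:
        nonlocal state, ll
        new_state, log_extra = propose(state, rng)
        new_ll = log_likelihood(new_state)
        if np.log(rng.random()) < beta * (new_ll - ll) + log_extra:
            state, ll = new_state, new_ll

    betas = power_betas(steps, alpha)
    lnm, per_step, se = _stepping_stone_core(step, lambda: ll, betas, samples_per_step, burnin, thin)
    return MarginalLikelihoodEstimate("generic", lnm, steps, per_step, se)


def compare_models(estimates: dict[str, MarginalLikelihoodEstimate]) -> pd.DataFrame:
    """delta-lnL table: best model scores 0, every other model the drop of
    its marginal log likelihood below the best; row order as given."""
    if not estimates:
        raise ValueError("no estimates to compare")
    best = max(e.log_marginal for e in estimates.values())
    return pd.DataFrame(
        {
            "model": list(estimates),
            "log_marginal": [e.log_marginal for e in estimates.values()],
            "delta_lnl": [best - e.log_marginal for e in estimates.values()],
            "mc_se": [e.mc_se for e in estimates.values()],
        }
    )
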