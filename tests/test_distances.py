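"""Binary CND, rate matrices, neighbour joining, hierarchical clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from suscape import distances as dist
from suscape.trees import Tree, random_tree


class TestBinaryCND:
    @pytest.mark.parametrize("a,b,counted", [(5, 3, 1), (5, 4, 0), (10, 2, 1), (2, 2, 0)])
    def test_threshold_two(self, a, b, counted):
        counts = dist.binary_cnd(np.array([[a, b]], float))
        assert counts[0, 1] == counted

    def test_identical_samples_zero(self):
        cn = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert (dist.binary_cnd(cn) == 0).all()

    @given(arrays(np.float64, (12, 4), elements=st.floats(0, 40)))
    def test_symmetric_zero_diagonal(self, cn):
        counts = dist.binary_cnd(cn)
        assert (counts == counts.T).all()
        assert (np.diag(counts) == 0).all()


class TestRates:
    def test_rate_arithmetic(self):
        counts = np.array([[0, 352], [352, 0]])
        rm = dist.cnd_rate(counts, 1408, ["a", "b"])
        assert rm.rates[0, 1] == 0.25

    def test_identical_cohort_ratio_undefined(self):
        cnd = dist.cnd_rate(np.zeros((3, 3)), 10, list("abc"))
        snp = dist.snp_rate(np.zeros((3, 100), dtype=np.uint8), list("abc"))
        with pytest.raises(ValueError):
            dist.rate_ratio(cnd, snp)

    def test_ratio_of_known_rates(self):
        labels = list("ab")
        cnd = dist.RateMatrix(labels, np.array([[0, 0.25], [0.25, 0]]), 1408)
        snp = dist.RateMatrix(labels, np.array([[0, 0.1], [0.1, 0]]), 10**6)
        assert np.isclose(dist.rate_ratio(cnd, snp)["mean"], 2.5)


# ---------------------------------------------------------------------------
# neighbour joining


def _all_topologies(names):
    """Every unrooted binary topology by sequential edge insertion."""
    if len(names) == 3:
        t = Tree.from_newick(f"({names[0]},{names[1]},{names[2]});")
        yield t
        return
    for sub in _all_topologies(names[:-1]):
        edges = sub.edges()
        for k in range(len(edges)):
            t = sub.copy()
            target = t.edges()[k]
            parent = target.parent
            from suscape.trees import Node

            mid = Node()
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add(target)
            mid.add(Node(names[-1]))
            yield t


def _least_squares_fit(tree, labels, d):
    """Residual of the best least-squares branch lengths for a topology."""
    leaves = {n: i for i, n in enumerate(tree.leaf_names())}
    edges = tree.edges()
    pairs = list(itertools.combinations(labels, 2))
    X = np.zeros((len(pairs), len(edges)))
    below = {}
    for node in tree.postorder():
        below[id(node)] = {node.name} if node.is_leaf else set().union(*[below[id(c)] for c in node.children])
    for r, (a, b) in enumerate(pairs):
        for c, e in enumerate(edges):
            side = below[id(e)]
            if (a in side) != (b in side):
                X[r, c] = 1.0
    y = np.array([d[labels.index(a), labels.index(b)] for a, b in pairs])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((X @ coef - y) ** 2))


class TestNJ:
    def test_printed_four_taxon_matrix_exact(self):
        """Additive matrix of ((A:1,B:2):1,(C:3,D:4)): topology AB|CD and
        the exact branch lengths."""
        labels = list("ABCD")
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = dist.nj_tree(d, labels)
        assert t.splits() == {frozenset({"C", "D"})}
        names, dm = t.distance_matrix()
        order = [names.index(x) for x in labels]
        assert np.allclose(dm[np.ix_(order, order)], d)
        lengths = {n.name: n.length for n in t.postorder() if n.is_leaf}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_resolved_exactly(self):
        d = np.array([[0, 2, 3], [2, 0, 3.4], [3, 3.4, 0]])
        t = dist.nj_tree(d, list("abc"))
        names, dm = t.distance_matrix()
        order = [names.index(x) for x in "abc"]
        assert np.allclose(dm[np.ix_(order, order)], d)

    def test_random_additive_matrices_match_brute_force(self):
        """NJ topology equals the unique zero-residual topology found by
        exhaustive enumeration, for 100 random 5-6 taxon additive matrices."""
        rng = np.random.default_rng(12)
        for rep in range(100):
            n = int(rng.integers(5, 7))
            labels = [f"T{i}" for i in range(n)]
            true = random_tree(labels, rng)
            for e in true.edges():
                e.length = float(rng.uniform(0.3, 2.5))
            names, d0 = true.distance_matrix()
            order = [names.index(x) for x in labels]
            d = d0[np.ix_(order, order)]
            nj = dist.nj_tree(d, labels)
            best, best_res = None, np.inf
            for cand in _all_topologies(labels):
                res = _least_squares_fit(cand, labels, d)
                if res < best_res:
                    best, best_res = cand.copy(), res
            assert best_res < 1e-18
            assert nj.rf_distance(best) == 0

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            dist.nj_tree(np.array([[0, 1], [2, 0]]), list("ab"))


class TestHierarchicalCluster:
    def test_identical_samples_join_at_height_zero(self):
        cn = np.array([[2.0, 2.0, 8.0], [4.0, 4.0, 1.0]])
        t = dist.hierarchical_cluster(cn, list("abc"))
        # a and b merge first with zero-length branches
        for node in t.postorder():
            if not node.is_leaf and {c.name for c in node.children} == {"a", "b"}:
                assert all(c.length == 0 for c in node.children)
                break
        else:
            pytest.fail("a,b cluster not found")

    def test_outlier_joins_last(self):
        cn = np.array([[2.0, 2.1, 9.0], [4.0, 4.1, 0.5], [3.0, 3.2, 7.7]])
        t = dist.hierarchical_cluster(cn, list("abc"))
        top_children = {frozenset(leaf.name for leaf in Tree(c).leaves()) if not c.is_leaf else frozenset({c.name}) for c in t.root.children}
        assert frozenset({"c"}) in top_children

    def test_ultrametric_matrix_agrees_with_nj_topology(self):
        """On ultrametric data (equidistant, well-separated cluster centres)
        NJ and complete-linkage clustering give the same unrooted topology."""
        rng = np.random.default_rng(5)
        centres = np.zeros((3, 30))
        centres[0, 0] = centres[1, 1] = centres[2, 2] = 10.0  # mutually equidistant
        assign = [0, 0, 1, 1, 2]
        cn = np.column_stack([centres[a] + rng.normal(0, 0.01, 30) for a in assign])
        labels = list("abcde")
        hc = dist.hierarchical_cluster(cn, labels)
        dm = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                dm[i, j] = np.linalg.norm(cn[:, i] - cn[:, j])
        nj = dist.nj_tree(dm, labels)
        assert nj.rf_distance(hc) == 0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        cn = rng.uniform(0, 8, size=(25, 5))
        labels = list("abcde")
        t1 = dist.hierarchical_cluster(cn, labels)
        perm = [3, 0, 4, 1, 2]
        t2 = dist.hierarchical_cluster(cn[:, perm], [labels[i] for i in perm])
        assert t1.rf_distance(t2) == 0
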