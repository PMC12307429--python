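"""Distances, neighbor joining, bootstrap supports, GRM and PCA."""

import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germcore import popstruct as ps
from germcore import synthetic_data as sd
from germcore.popstruct import DistanceMatrix
from tests.conftest import make_matrix


def random_additive_tree(n, seed, tns):
    """Random unrooted binary topology with branch lengths in [0.1, 1]."""
    rng = np.random.default_rng(seed)
    py_rng = random.Random(seed)
    taxa = [t.label for t in tns]
    pool = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa[:n]]
    while len(pool) > 3:
        a = pool.pop(py_rng.randrange(len(pool)))
        b = pool.pop(py_rng.randrange(len(pool)))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = rng.uniform(0.1, 1.0)
        b.edge.length = rng.uniform(0.1, 1.0)
        pool.append(parent)
    root = dendropy.Node()
    for x in pool:
        root.add_child(x)
        x.edge.length = rng.uniform(0.1, 1.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_matrix(tree, labels):
    tns = tree.taxon_namespace
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                tns.get_taxon(labels[i]), tns.get_taxon(labels[j]))
    return d


class TestSquaredDistance:
    def test_identical_rows_have_zero_distance(self):
        d = ps.squared_distance(make_matrix([[0, 1, 2], [0, 1, 2]]))
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_have_unit_distance(self):
        d = ps.squared_distance(make_matrix([[0] * 6, [2] * 6]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_brute_force(self):
        rng = np.random.default_rng(8)
        dos = rng.choice([-1, 0, 1, 2], size=(5, 20), p=[0.1, 0.3, 0.3, 0.3])
        m = make_matrix(dos)
        d = ps.squared_distance(m)
        for i in range(5):
            for j in range(5):
                shared = (dos[i] >= 0) & (dos[j] >= 0)
                expect = np.mean(
                    ((dos[i][shared] - dos[j][shared]) / 2.0) ** 2)
                assert abs(d.values[i, j] - expect) < 1e-12
                assert d.pair_loci[i, j] == shared.sum()

    def test_disconnected_pair_is_an_error(self):
        m = make_matrix([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="s0.*s1"):
            ps.squared_distance(m)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_locus_and_sample_order(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, (6, 15)).astype(np.int8)
        m = make_matrix(dos)
        base = ps.squared_distance(m).values
        lperm = rng.permutation(15)
        sperm = rng.permutation(6)
        shuffled = make_matrix(dos[np.ix_(sperm, lperm)])
        new = ps.squared_distance(shuffled).values
        assert np.allclose(new, base[np.ix_(sperm, sperm)], atol=1e-12)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d = a+b, a+c, b+c with a=1, b=2, c=3
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = ps.nj(DistanceMatrix(["A", "B", "C"], d, np.ones((3, 3), int)))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_quartet_recovers_topology_and_lengths(self):
        # tree ((A:1,B:2):1.5,C:3,D:4) -> additive distances
        d = np.array([
            [0.0, 3.0, 5.5, 6.5],
            [3.0, 0.0, 6.5, 7.5],
            [5.5, 6.5, 0.0, 7.0],
            [6.5, 7.5, 7.0, 0.0],
        ])
        labels = ["A", "B", "C", "D"]
        tree = ps.nj(DistanceMatrix(labels, d, np.ones((4, 4), int)))
        back = patristic_matrix(tree, labels)
        assert np.abs(back - d).max() < 1e-9

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (12, 2), (10, 3)])
    def test_recovers_random_additive_trees(self, n, seed):
        labels = [f"t{i}" for i in range(n)]
        tns = dendropy.TaxonNamespace(labels)
        true = random_additive_tree(n, seed, tns)
        d = patristic_matrix(true, labels)
        est = ps.nj(DistanceMatrix(labels, d, np.ones((n, n), int)),
                    taxon_namespace=tns)
        assert dendropy.calculate.treecompare.symmetric_difference(
            true, est) == 0

    def test_matches_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on an
        additive instance (both must invert the generating tree)."""
        skbio = pytest.importorskip("skbio")
        labels = [f"t{i}" for i in range(7)]
        tns = dendropy.TaxonNamespace(labels)
        true = random_additive_tree(7, 99, tns)
        d = patristic_matrix(true, labels)
        ours = ps.nj(DistanceMatrix(labels, d, np.ones((7, 7), int)),
                     taxon_namespace=tns)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        theirs_dp = dendropy.Tree.get(
            data=str(theirs), schema="newick", taxon_namespace=tns)
        theirs_dp.is_rooted = False
        assert dendropy.calculate.treecompare.symmetric_difference(
            ours, theirs_dp) == 0

    def test_tied_ultrametric_input_is_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        labels = list("abcde")
        newicks = set()
        for _ in range(3):
            t = ps.nj(DistanceMatrix(labels, d.copy(),
                                     np.ones((5, 5), int)))
            newicks.add(t.as_string(schema="newick"))
        assert len(newicks) == 1

    def test_rejects_fewer_than_three(self):
        with pytest.raises(ValueError, match=">= 3"):
            ps.nj(DistanceMatrix(["a", "b"], np.zeros((2, 2)),
                                 np.ones((2, 2), int)))


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, small_filtered):
        tree = ps.bootstrap_support(small_filtered, n_reps=1, seed=4)
        sups = {nd.support for nd in tree.preorder_node_iter()
                if getattr(nd, "support", None) is not None}
        assert sups <= {0.0, 100.0}

    def test_seeded_determinism(self, small_filtered):
        t1 = ps.bootstrap_support(small_filtered, n_reps=10, seed=3)
        t2 = ps.bootstrap_support(small_filtered, n_reps=10, seed=3)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_rejects_zero_replicates(self, small_filtered):
        with pytest.raises(ValueError, match="n_reps"):
            ps.bootstrap_support(small_filtered, n_reps=0)


class TestGrm:
    def test_identical_rows_give_constant_matrix(self):
        # identical heterozygous rows: every locus polymorphic (p = 0.5)
        m = make_matrix(np.ones((4, 5)))
        g = ps.grm(m)
        assert np.allclose(g, g[0, 0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        dos = rng.integers(0, 3, (6, 50)).astype(np.int8)
        colsum = dos.sum(axis=0)
        dos[0, colsum == 0] = 1   # avoid monomorphic columns
        dos[0, colsum == 12] = 1
        m = make_matrix(dos)
        g = ps.grm(m)
        p = m.alt_allele_frequency()
        expect = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                expect[i, j] = np.mean(
                    (dos[i] - 2 * p) * (dos[j] - 2 * p) / (2 * p * (1 - p)))
        assert np.abs(g - expect).max() < 1e-10

    def test_diagonal_mean_near_one_under_hardy_weinberg(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 5000)
        dos = rng.binomial(2, p, size=(40, 5000)).astype(np.int8)
        mono = (dos.sum(axis=0) == 0) | (dos.sum(axis=0) == 80)
        m = make_matrix(dos[:, ~mono])
        assert np.diag(ps.grm(m)).mean() == pytest.approx(1.0, abs=0.1)

    def test_rejects_monomorphic_locus(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ps.grm(make_matrix([[0, 1], [0, 1], [0, 2]]))


class TestPca:
    def test_rank_one_matrix(self):
        v = np.array([1.0, -1.0, 2.0])
        g = np.outer(v, v)
        res = ps.pca(g, k=3)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert np.abs(res.variance_explained[1:]).max() < 1e-12

    def test_eigen_residual_and_orthogonality(self, small_filtered):
        g = ps.grm(small_filtered)
        res = ps.pca(g, k=5, sample_ids=small_filtered.sample_ids)
        lam = res.variance_explained * np.trace(g)
        for c in range(5):
            v = res.coordinates[:, c]
            norm = np.linalg.norm(v)
            if norm < 1e-12:
                continue
            v = v / norm
            assert np.linalg.norm(g @ v - lam[c] * v) < 1e-8
        vt = res.coordinates / np.linalg.norm(res.coordinates, axis=0)
        off = vt.T @ vt - np.eye(5)
        assert np.abs(off).max() < 1e-8

    def test_variance_explained_non_increasing(self, small_filtered):
        res = ps.pca(ps.grm(small_filtered), k=10)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_rejects_k_above_n(self):
        with pytest.raises(ValueError, match="k"):
            ps.pca(np.eye(3), k=4)

    def test_pc1_separates_synthetic_subpopulations(self, default_population):
        cfg, filtered = default_population
        labels = sd.subpopulation_labels(cfg).astype(bool)
        res = ps.pca(ps.grm(filtered), k=2,
                     sample_ids=filtered.sample_ids)
        sign = res.coordinates[:, 0] > 0
        agree = max((sign == labels).mean(), (sign != labels).mean())
        assert agree >= 0.95
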