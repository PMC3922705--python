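import itertools

import dendropy
from dendropy.calculate import treecompare
import numpy as np
import pytest

from httdetect.distances import DistanceMatrix
from httdetect.io_formats import read_newick, write_newick
from httdetect.phylo_concordance import (
    copy_monophyly,
    dollo_min_losses,
    nj_tree,
    rf_distance,
)
from httdetect.synthetic_data import simulate_species_tree


def dm_from(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(tuple(labels), d, np.ones_like(d, dtype=int))


def patristic_dm(tree):
    """Additive matrix from a tree's path lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = pdm.distance(taxa[a], taxa[b])
    return DistanceMatrix(tuple(labels), d, np.ones((n, n), dtype=int))


def rf_via_dendropy(t1, t2):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        # additive three-point formulas: la = (dab + dac - dbc)/2 etc.
        d = [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
        t = nj_tree(dm_from(["a", "b", "c"], d))
        bl = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert bl["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert bl["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert bl["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_five_taxon_additive_recovery(self):
        src = read_newick("((A:1,B:2):1,(C:1,(D:2,E:1):1):2);")
        t = nj_tree(patristic_dm(src))
        assert rf_via_dendropy(t, src) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_matrices_recover_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        src = simulate_species_tree(n, 10.0, seed=seed + 100)
        # jitter branch lengths so the matrix is additive but not ultrametric
        for e in src.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * rng.uniform(0.5, 2.0) + 0.01
        t = nj_tree(patristic_dm(src))
        assert rf_via_dendropy(t, src) == 0

    def test_identical_sequences_give_zero_length_cherry(self):
        d = [[0, 0, 0.4, 0.4], [0, 0, 0.4, 0.4], [0.4, 0.4, 0, 0.2], [0.4, 0.4, 0.2, 0]]
        t = nj_tree(dm_from(list("abcd"), d))
        bl = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert bl["a"] == pytest.approx(0.0)
        assert bl["b"] == pytest.approx(0.0)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(dm_from(["a", "b"], [[0, 1], [1, 0]]))

    def test_undefined_entries_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(DistanceMatrix(("a", "b", "c"), d, np.ones((3, 3), dtype=int)))


def brute_force_dollo(tree, presence):
    """Exhaustive search over loss placements below the MRCA of present
    leaves; returns the minimum number of losses reproducing the pattern."""
    present = {l for l, v in presence.items() if v}
    mrca = tree.mrca(taxon_labels=sorted(present))
    nodes = [nd for nd in mrca.preorder_iter() if nd is not mrca]
    best = None
    for k in range(len(nodes) + 1):
        for cut in itertools.combinations(nodes, k):
            state = {}
            ok = True
            for nd in mrca.preorder_iter():
                if nd is mrca:
                    state[id(nd)] = True
                else:
                    state[id(nd)] = state[id(nd.parent_node)] and nd not in cut
                if nd.is_leaf():
                    want = presence.get(nd.taxon.label, False)
                    if state[id(nd)] != want:
                        ok = False
                        break
            if ok:
                return k
    return best


class TestDolloMinLosses:
    def rooted(self, nwk):
        t = read_newick(nwk)
        t.is_rooted = True
        return t

    def test_all_present_no_losses(self):
        t = self.rooted("((A,B),(C,D));")
        assert dollo_min_losses(t, dict.fromkeys("ABCD", True)) == (1, 0)

    def test_alternating_pattern_two_losses(self):
        t = self.rooted("((A,B),(C,D));")
        pres = {"A": True, "B": False, "C": True, "D": False}
        assert dollo_min_losses(t, pres) == (1, 2)

    def test_single_present_leaf_no_losses(self):
        t = self.rooted("((A,B),(C,D));")
        assert dollo_min_losses(t, {"A": True}) == (1, 0)

    def test_no_present_leaf_rejected(self):
        t = self.rooted("((A,B),(C,D));")
        with pytest.raises(ValueError):
            dollo_min_losses(t, {})

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        t = simulate_species_tree(n, 1.0, seed=seed)
        t.is_rooted = True
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        for _ in range(6):
            pres = {l: bool(rng.random() < 0.5) for l in labels}
            if not any(pres.values()):
                pres[labels[0]] = True
            _, losses = dollo_min_losses(t, pres)
            assert losses == brute_force_dollo(t, pres)


class TestCopyMonophyly:
    def test_paired_species_both_monophyletic(self):
        t = read_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        res = copy_monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert res["monophyly"] == {"A": True, "B": True}
        assert res["n_monophyletic"] == 2

    def test_interleaved_species_not_monophyletic(self):
        t = read_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        res = copy_monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        # verified by enumerating all edges: no split isolates {a1,a2}
        assert res["monophyly"] == {"A": False, "B": False}

    def test_singleton_reported_separately(self):
        t = read_newick("((a1:1,a2:1):1,(b1:1,c1:1):1);")
        res = copy_monophyly(t, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        assert res["singletons"] == ["B", "C"]
        assert res["n_species_with_multiple_copies"] == 1

    def test_missing_mapping_rejected(self):
        t = read_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        with pytest.raises(ValueError, match="b2"):
            copy_monophyly(t, {"a1": "A", "a2": "A", "b1": "B"})

    def test_invariant_to_rerooting(self):
        nwk = "((a1:1,(a2:1,b1:1):1):1,(b2:1,(c1:1,c2:1):1):1);"
        mapping = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        t1 = read_newick(nwk)
        r1 = copy_monophyly(t1, mapping)
        t2 = read_newick(nwk)
        leaf = next(lf for lf in t2.leaf_node_iter() if lf.taxon.label == "c1")
        t2.reroot_at_edge(leaf.edge, update_bipartitions=True)
        r2 = copy_monophyly(t2, mapping)
        assert r1["monophyly"] == r2["monophyly"]


def brute_force_rf(t1, t2):
    """Independent bipartition comparison via explicit leaf-subset splits."""
    def splits(tree):
        leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        out = set()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None or nd.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            pair = frozenset({below, leaves - below})
            if min(len(s) for s in pair) >= 2:
                out.add(pair)
        return out

    return len(splits(t1) ^ splits(t2))


class TestRFDistance:
    def test_identical_trees(self):
        t1 = read_newick("((A,B),(C,D),E);")
        t2 = read_newick("((A,B),(C,D),E);")
        rf, max_rf = rf_distance(t1, t2)
        assert (rf, max_rf) == (0, 4)

    def test_four_taxon_swap(self):
        t1 = read_newick("((A,B),(C,D));")
        t2 = read_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == (2, 2)

    def test_caterpillar_vs_balanced(self):
        cat = read_newick("(A,(B,(C,(D,(E,F)))));")
        bal = read_newick("(((A,B),(C,D)),(E,F));")
        rf, _ = rf_distance(cat, bal)
        assert rf == brute_force_rf(cat, bal)

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError, match="E"):
            rf_distance(read_newick("((A,B),(C,D));"), read_newick("((A,B),(C,E));"))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_and_library(self, seed):
        t1 = simulate_species_tree(7, 1.0, seed=seed)
        t2 = simulate_species_tree(7, 1.0, seed=seed + 50)
        rf, max_rf = rf_distance(t1, t2)
        assert rf == brute_force_rf(t1, t2)
        assert rf == rf_via_dendropy(t1, t2)
        assert max_rf == 2 * (7 - 3)

    def test_metric_properties_spot_check(self):
        trees = [simulate_species_tree(6, 1.0, seed=s) for s in (1, 2, 3)]
        d = {}
        for i, a in enumerate(trees):
            for j, b in enumerate(trees):
                d[i, j] = rf_distance(a, b)[0] if i != j else 0
        assert all(d[i, j] == d[j, i] for i in range(3) for j in range(3))
        assert d[0, 2] <= d[0, 1] + d[1, 2]
        assert rf_distance(trees[0], trees[0])[0] == 0
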