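"""Independent brute-force oracles used by the acceptance script.

These deliberately avoid the package's own tree code paths: topology
comparison goes through dendropy, Dollo losses through exhaustive search
over loss placements, and RF through explicit leaf-subset enumeration.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from httdetect.distances import DistanceMatrix
from httdetect.io_formats import write_newick


def patristic_dm(tree: dendropy.Tree) -> DistanceMatrix:
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


def rf_topologically_equal(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b) == 0


def brute_force_dollo(tree: dendropy.Tree, presence: dict[str, bool]) -> int:
    present = {l for l, v in presence.items() if v}
    mrca = tree.mrca(taxon_labels=sorted(present))
    nodes = [nd for nd in mrca.preorder_iter() if nd is not mrca]
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
                    if state[id(nd)] != presence.get(nd.taxon.label, False):
                        ok = False
                        break
            if ok:
                return k
    raise AssertionError("unreachable: full cut always reproducible")


def brute_force_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
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
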