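"""Tree-based HTT evidence: NJ copy trees, Dollo patchiness, copy monophyly
and Robinson–Foulds host/TE incongruence.

Trees are dendropy objects throughout. Neighbor joining is the classic
Saitou–Nei agglomeration on the Q criterion; Dollo parsimony places a single
gain at the MRCA of the present leaves and counts the minimum number of
losses explaining the presence pattern — the quantity that makes a "patchy"
taxonomic distribution precise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix

logger = logging.getLogger("httdetect")


@dataclass(frozen=True)
class PresenceMatrix:
    """Species-by-family presence/absence, species matching a host tree."""

    table: pd.DataFrame  # bool, index = species, columns = te families

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    @property
    def te_families(self) -> list[str]:
        return list(self.table.columns)

    def presence(self, family: str) -> dict[str, bool]:
        return {sp: bool(v) for sp, v in self.table[family].items()}

    def validate_against(self, tree: dendropy.Tree) -> None:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if leaves != set(self.species):
            raise ValueError(
                "species set does not match tree leaves; difference: "
                f"{sorted(leaves ^ set(self.species))}"
            )

    def to_tsv(self, path) -> None:
        self.table.astype(int).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
        return cls(df)


@dataclass(frozen=True)
class ConcordanceReport:
    family: str
    dollo_losses: int
    n_monophyletic_species: int
    n_species_with_multiple_copies: int
    rf_distance: int
    max_rf: int

    def __post_init__(self) -> None:
        if not 0 <= self.rf_distance <= max(self.max_rf, 0):
            raise ValueError("rf_distance out of [0, max_rf]")
        if self.dollo_losses < 0:
            raise ValueError("dollo_losses must be >= 0")


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Saitou–Nei) unrooted tree from a distance matrix.

    Ties in the Q matrix break toward the lowest index pair for
    determinism. Negative branch lengths are clamped to zero with the
    deficit logged.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    undef = dm.undefined_pairs()
    if undef:
        raise ValueError(f"undefined distances for pairs: {undef}")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    D = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("NJ: clamped negative branch length %.6g to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = clamp(li)
        nj_.edge.length = clamp(lj)
        # grow the matrix with the new internal node
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final join: hang the remaining node off the last internal node with
    # the full residual distance (keeps the tree unrooted, no fake midpoint)
    i, j = active
    hub, other = (j, i) if not nodes[j].is_leaf() else (i, j)
    nodes[hub].add_child(nodes[other])
    nodes[other].edge.length = clamp(D[i, j])
    tree.seed_node = nodes[hub]
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def dollo_min_losses(
    tree: dendropy.Tree, presence: dict[str, bool]
) -> tuple[int, int]:
    """Minimum loss count under Dollo parsimony (single gain).

    The gain is placed at the MRCA of the present leaves; losses are the
    maximal clades below that ancestor containing no present leaf. Returns
    ``(gains, losses)`` with gains fixed at 1.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(presence) - leaves
    if missing:
        raise ValueError(f"presence labels not in tree: {sorted(missing)}")
    present = {lab for lab in leaves if presence.get(lab, False)}
    if not present:
        raise ValueError("no present leaf: nothing to explain")

    mrca = tree.mrca(taxon_labels=sorted(present))
    has_present: dict[int, bool] = {}
    for nd in mrca.postorder_iter():
        if nd.is_leaf():
            has_present[id(nd)] = nd.taxon.label in present
        else:
            has_present[id(nd)] = any(has_present[id(c)] for c in nd.child_nodes())
    losses = 0
    for nd in mrca.preorder_iter():
        if has_present[id(nd)]:
            losses += sum(1 for c in nd.child_nodes() if not has_present[id(c)])
    return 1, losses


def _bipartitions(tree: dendropy.Tree) -> tuple[set[frozenset[str]], frozenset[str]]:
    """Non-trivial splits of an (effectively unrooted) tree.

    Each split is canonicalised as the side not containing the
    lexicographically smallest leaf label.
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits, leaves


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, int]:
    """Robinson–Foulds symmetric difference on non-trivial bipartitions.

    ``max_rf`` is 2*(n-3), the maximum for binary unrooted trees on n
    leaves. Leaf sets must match exactly.
    """
    s1, l1 = _bipartitions(t1)
    s2, l2 = _bipartitions(t2)
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    rf = len(s1 ^ s2)
    max_rf = 2 * max(len(l1) - 3, 0)
    return rf, max_rf


def copy_monophyly(
    copy_tree: dendropy.Tree, species_of_copy: dict[str, str]
) -> dict:
    """Per-species monophyly of TE copies in an unrooted copy tree.

    A species is monophyletic iff some edge splits exactly its copies from
    everything else. Species with a single copy are trivially monophyletic
    and reported separately as singletons, excluded from the count of
    species with multiple copies.
    """
    leaves = {lf.taxon.label for lf in copy_tree.leaf_node_iter()}
    unmapped = leaves - set(species_of_copy)
    if unmapped:
        raise ValueError(f"copy labels missing from species map: {sorted(unmapped)}")
    by_species: dict[str, set[str]] = {}
    for copy in leaves:
        by_species.setdefault(species_of_copy[copy], set()).add(copy)

    # every clade (leaf-set below an edge), both orientations of each split
    sides: set[frozenset[str]] = set()
    for nd in copy_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        sides.add(side)
        sides.add(frozenset(leaves) - side)

    monophyly: dict[str, bool] = {}
    singletons: list[str] = []
    for sp, copies in sorted(by_species.items()):
        if len(copies) == 1:
            singletons.append(sp)
            continue
        monophyly[sp] = frozenset(copies) in sides
    return {
        "monophyly": monophyly,
        "singletons": singletons,
        "n_monophyletic": sum(monophyly.values()),
        "n_species_with_multiple_copies": len(monophyly),
    }
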