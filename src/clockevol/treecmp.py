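"""Tree building, ultrametric conversion and tanglegram incongruence metrics.

The tanglegram entanglement statistic quantifies leaf-order discordance
between two ultrametric trees: with leaves matched by label, E is the sum of
|rank_a - rank_b|^p over leaves, normalised by the maximum achievable under a
fully reversed order, after a deterministic greedy untangling pass (node
flips accepted when they reduce E).  Robinson-Foulds counts bipartitions
present in exactly one tree.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError


# ---------------------------------------------------------------------------
# neighbor joining (fallback when no externally inferred tree is supplied)


def nj_tree(distances: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are floored at 0 with the mass moved to the
    sibling branch (the standard correction).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ConfigurationError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ConfigurationError("distance matrix must be symmetric")
    if len(labels) != D.shape[0]:
        raise ConfigurationError("labels must match matrix size")

    csv = io.StringIO()
    csv.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        csv.write(lab + "," + ",".join(f"{x:.12g}" for x in D[i]) + "\n")
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        csv, delimiter=",", is_allow_new_taxa=True
    )
    tree = pdm.nj_tree()
    _floor_negative_branches(tree)
    return tree


def _floor_negative_branches(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            if bl < 0:
                siblings = [c for c in node.child_nodes() if c is not child]
                for sib in siblings:
                    sib.edge.length = (sib.edge.length or 0.0) + bl / len(siblings)
                child.edge.length = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0


# ---------------------------------------------------------------------------
# ultrametric conversion


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    return t


def ultrametricize(tree: dendropy.Tree, assume_rooted: bool = True) -> dendropy.Tree:
    """Clock-project a tree: every node sits at the mean root-to-tip depth of
    its subtree, clipped below its parent, so all root-to-tip paths are equal.

    A deterministic stand-in for rate-smoothing dating methods, adequate when
    the ultrametric tree is only used for dendrogram comparison.
    """
    t = tree.clone(depth=1)
    if not assume_rooted and len(t.seed_node.child_nodes()) > 2:
        t = midpoint_root(t)
    # height = mean distance from node to its descendant tips
    heights: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            vals = []
            for child in node.child_nodes():
                vals.append(heights[child] + (child.edge.length or 0.0))
            heights[node] = float(np.mean(vals))
    # clip children below parents, then rewrite branch lengths
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is not None and heights[node] > heights[parent]:
            heights[node] = heights[parent]
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            node.edge.length = heights[parent] - heights[node]
    return t


def root_to_tip_spread(tree: dendropy.Tree) -> float:
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    return float(max(depths) - min(depths))


# ---------------------------------------------------------------------------
# entanglement


def _leaf_order(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _entanglement_given_orders(
    order_a: list[str], order_b: list[str], norm_power: float
) -> float:
    rank_b = {lab: i for i, lab in enumerate(order_b)}
    n = len(order_a)
    disp = sum(abs(i - rank_b[lab]) ** norm_power for i, lab in enumerate(order_a))
    worst = sum(abs(i - (n - 1 - i)) ** norm_power for i in range(n))
    return disp / worst if worst > 0 else 0.0


def entanglement(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    norm_power: float = 1.0,
    untangle: bool = True,
    max_sweeps: int = 25,
) -> float:
    """Entanglement in [0, 1] between two trees on the same tip set.

    With ``untangle`` the two-sided greedy rotation heuristic flips children
    of internal nodes (post-order, first-improvement, alternating trees)
    until no flip helps or ``max_sweeps`` sweeps have run.
    """
    ta, tb = tree_a.clone(depth=1), tree_b.clone(depth=1)
    la, lb = set(_leaf_order(ta)), set(_leaf_order(tb))
    if la != lb:
        raise ConfigurationError(f"tip sets differ: {sorted(la ^ lb)}")

    def current():
        return _entanglement_given_orders(_leaf_order(ta), _leaf_order(tb), norm_power)

    best = current()
    if not untangle:
        return best
    for _ in range(max_sweeps):
        improved = False
        for t in (ta, tb):
            for node in t.postorder_internal_node_iter():
                children = node.child_nodes()
                if len(children) < 2:
                    continue
                node.set_child_nodes(list(reversed(children)))
                e = current()
                if e < best - 1e-15:
                    best = e
                    improved = True
                else:
                    node.set_child_nodes(children)
        if not improved:
            break
    return best


def tanglegram_table(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> pd.DataFrame:
    """Leaf ranks in both trees (for export/plotting)."""
    order_a = _leaf_order(tree_a)
    rank_b = {lab: i for i, lab in enumerate(_leaf_order(tree_b))}
    return pd.DataFrame(
        {"leaf": order_a, "rank_a": range(len(order_a)), "rank_b": [rank_b[l] for l in order_a]}
    )


# ---------------------------------------------------------------------------
# Robinson-Foulds


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Number of bipartitions present in exactly one of the two trees."""
    la = {lf.taxon.label for lf in tree_a.leaf_node_iter()}
    lb = {lf.taxon.label for lf in tree_b.leaf_node_iter()}
    if la != lb:
        raise ConfigurationError(f"tip sets differ: {sorted(la ^ lb)}")
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    b = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    # compare unrooted topologies (the classic RF bound 2(n-3) applies)
    for t in (a, b):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))
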