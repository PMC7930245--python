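"""Score recovered clusters and clone trees against a synthetic truth.

Recovered clusters are matched to truth nodes by majority vote over their
member mutations; a truth clone counts as recovered when some cluster's
majority maps to it. Parent recovery then compares the recovered tree's
parent relation, with the (possibly synthetic) recovered root standing in
for the ubiquitous embryonic root — whose own mutations sit at VAF ~0.5 in
every tissue and are therefore absorbed by the germline filter, exactly as
in real multi-tissue data.
"""

from __future__ import annotations

import pandas as pd

from .cluster import MutationCluster
from .simulate import TruthTree
from .tree import CloneTree, clone_sizes


def map_clusters_to_truth(clusters: list[MutationCluster], truth: TruthTree) -> dict[int, int]:
    """cluster_id -> truth node id by majority vote over member mutations."""
    out = {}
    for cl in clusters:
        nodes = truth.assignment.reindex(cl.members).dropna()
        if len(nodes):
            out[cl.cluster_id] = int(nodes.value_counts().idxmax())
    return out


def _node_of(tree_node: int, mapping: dict[int, int], truth_root: int) -> int | None:
    from .tree import SYNTHETIC_ROOT

    if tree_node == SYNTHETIC_ROOT:
        return truth_root
    return mapping.get(tree_node)


def parent_recovery(
    tree: CloneTree, clusters: list[MutationCluster], truth: TruthTree
) -> pd.DataFrame:
    """Per non-root truth clone: was it recovered with the right parent?

    Returns a DataFrame indexed by truth node with columns ``recovered``
    (a cluster maps to the node) and ``parent_correct``.
    """
    mapping = map_clusters_to_truth(clusters, truth)
    root = truth.root
    node_to_cluster: dict[int, int] = {}
    for cid, node in mapping.items():
        if node not in node_to_cluster:
            node_to_cluster[node] = cid
        else:  # keep the larger cluster as the node's representative
            sizes = {c.cluster_id: c.burden for c in clusters}
            if sizes[cid] > sizes[node_to_cluster[node]]:
                node_to_cluster[node] = cid

    rows = {}
    for node in truth.nodes:
        if node == root:
            continue
        cid = node_to_cluster.get(node)
        if cid is None or cid not in tree.parents:
            rows[node] = {"recovered": False, "parent_correct": False}
            continue
        parent_node = _node_of(tree.parents[cid], mapping, root)
        rows[node] = {
            "recovered": True,
            "parent_correct": parent_node == truth.parents[node],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def clone_size_errors(
    tree: CloneTree, clusters: list[MutationCluster], truth: TruthTree
) -> pd.DataFrame:
    """|recovered - true| private clone fraction for matched nodes x samples."""
    mapping = map_clusters_to_truth(clusters, truth)
    truth_cs = clone_sizes(truth)
    rec_cs = tree.clone_size
    rows = {}
    from .tree import SYNTHETIC_ROOT

    for tree_node in tree.nodes:
        node = _node_of(tree_node, mapping, truth.root)
        if node is None or node in rows:
            continue
        if tree_node == SYNTHETIC_ROOT and truth.root not in truth_cs.index:
            continue
        err = (rec_cs.loc[tree_node] - truth_cs.loc[node]).abs()
        rows[node] = err
    return pd.DataFrame(rows).T.sort_index()


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (contingency form)."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    n = len(a)
    if n != len(b):
        raise ValueError("label vectors differ in length")
    ct = pd.crosstab(a, b).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(ct).sum()
    sum_a = comb(ct.sum(axis=1)).sum()
    sum_b = comb(ct.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
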