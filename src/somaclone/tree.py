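"""Reconcile mutation clusters into a clone tree under the pigeonhole rule.

In every sample, the cellular prevalences of daughter clones can never sum
to more than their parent's prevalence. The builder places clusters
greedily in descending mean-prevalence order, attaching each to the
deepest already-placed node that can both contain it (parent prevalence >=
cluster prevalence, per sample) and still has the spare capacity for it
(parent prevalence minus existing children), all within a tolerance
``epsilon`` that absorbs binomial sampling noise at ~30-40x depth.

Reported per node and sample: cellular prevalence, the private clone size
(prevalence minus the summed prevalence of the children), and the number
of mutations on the branch above the node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import MutationCluster

DEFAULT_EPSILON = 0.05

#: node id used for an inserted synthetic unit root
SYNTHETIC_ROOT = -1


class PigeonholeInfeasibleError(ValueError):
    """A cluster admits no parent under containment + capacity; the message
    lists, per candidate parent, the first violated sample."""


def vaf_to_prevalence(theta_hat) -> np.ndarray | pd.Series | float:
    """Diploid heterozygous mapping: prevalence = min(1, 2 * VAF).

    The cap absorbs sampling noise that pushes a clonal VAF above 0.5.
    """
    return np.minimum(1.0, 2.0 * np.asarray(theta_hat)) if np.ndim(theta_hat) else min(
        1.0, 2.0 * float(theta_hat)
    )


@dataclass
class CloneTree:
    """Rooted clone tree with per-sample prevalence and private fractions."""

    parents: dict[int, int | None]
    prevalence: pd.DataFrame  # nodes x samples
    burden: dict[int, int]
    epsilon: float
    members: dict[int, list[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[int]:
        return list(self.parents)

    @property
    def root(self) -> int:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        return roots[0]

    def children(self, node: int) -> list[int]:
        return [n for n, p in self.parents.items() if p == node]

    def depth(self, node: int) -> int:
        d = 0
        p = self.parents[node]
        while p is not None:
            d += 1
            p = self.parents[p]
        return d

    @property
    def clone_size(self) -> pd.DataFrame:
        return clone_sizes(self)

    # -- serialisation ------------------------------------------------

    def to_json(self) -> str:
        cs = self.clone_size
        return json.dumps(
            {
                "epsilon": self.epsilon,
                "nodes": [
                    {
                        "id": n,
                        "parent": self.parents[n],
                        "burden": int(self.burden.get(n, 0)),
                        "prevalence": {
                            s: round(float(self.prevalence.loc[n, s]), 6)
                            for s in self.prevalence.columns
                        },
                        "clone_size_pct": {
                            s: round(100.0 * float(cs.loc[n, s]), 2)
                            for s in cs.columns
                        },
                    }
                    for n in self.nodes
                ],
            },
            indent=1,
            sort_keys=True,
        )

    def to_newick(self) -> str:
        """Newick with node names ``c<id>`` and branch lengths = burdens."""

        def name(n: int) -> str:
            return "root" if n == SYNTHETIC_ROOT else f"c{n}"

        def rec(n: int) -> str:
            kids = sorted(self.children(n))
            label = f"{name(n)}:{self.burden.get(n, 0)}"
            if not kids:
                return label
            return "(" + ",".join(rec(k) for k in kids) + ")" + label

        return rec(self.root) + ";"

    def to_dot(self) -> str:
        """Graphviz description with burden and clone-size annotations."""
        cs = self.clone_size
        lines = ["digraph clone_tree {", "  node [shape=circle];"]
        for n in self.nodes:
            sizes = ", ".join(f"{s}:{100 * cs.loc[n, s]:.0f}%" for s in cs.columns)
            lines.append(
                f'  n{n} [label="{("root" if n == SYNTHETIC_ROOT else f"c{n}")}'
                f'\\n{self.burden.get(n, 0)} muts\\n{sizes}"];'
            )
        for n, p in self.parents.items():
            if p is not None:
                lines.append(f"  n{p} -> n{n};")
        lines.append("}")
        return "\n".join(lines)


def clone_sizes(tree: CloneTree) -> pd.DataFrame:
    """Private fraction per node and sample: prevalence minus children's sum."""
    cs = tree.prevalence.copy().astype(float)
    for n in tree.nodes:
        for c in tree.children(n):
            cs.loc[n] -= tree.prevalence.loc[c]
    return cs.clip(lower=0.0)


def check_pigeonhole(tree, epsilon: float = 0.0) -> tuple[bool, list[dict]]:
    """Verify sum(children prevalence) <= parent prevalence + epsilon everywhere.

    Works on any tree-like object exposing ``parents`` (node -> parent) and
    ``prevalence`` (nodes x samples DataFrame); deliberately independent of
    how the tree was built.
    """
    prev = tree.prevalence
    violations = []
    for node in tree.parents:
        kids = [n for n, p in tree.parents.items() if p == node]
        if not kids:
            continue
        child_sum = prev.loc[kids].sum(axis=0)
        for s in prev.columns:
            if child_sum[s] > prev.loc[node, s] + epsilon:
                violations.append(
                    {
                        "node": node,
                        "sample": s,
                        "parent_prevalence": float(prev.loc[node, s]),
                        "children_sum": float(child_sum[s]),
                    }
                )
    return (len(violations) == 0), violations


def build_tree(
    clusters: list[MutationCluster], epsilon: float = DEFAULT_EPSILON
) -> CloneTree:
    """Greedy pigeonhole reconciliation of clusters into a rooted tree.

    Clusters are processed in descending mean-prevalence order. The first
    becomes the root if it is (near-)clonal in every sample; otherwise a
    synthetic unit root is inserted. Each remaining cluster attaches to
    the deepest admissible parent — containment and spare capacity within
    ``epsilon`` in every sample — with ties broken by minimal total slack.
    A cluster with no admissible parent raises
    :class:`PigeonholeInfeasibleError` naming the violating samples.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    samples = list(clusters[0].prevalence.index)
    order = sorted(
        clusters, key=lambda c: (-float(np.mean(c.prevalence)), c.cluster_id)
    )

    prev: dict[int, np.ndarray] = {}
    parents: dict[int, int | None] = {}
    burden: dict[int, int] = {}
    members: dict[int, list[str]] = {}
    child_sum: dict[int, np.ndarray] = {}

    first = order[0]
    if float(np.min(first.prevalence)) >= 1.0 - epsilon:
        root = first.cluster_id
        prev[root] = first.prevalence.to_numpy(float)
        burden[root] = first.burden
        members[root] = list(first.members)
        rest = order[1:]
    else:
        root = SYNTHETIC_ROOT
        prev[root] = np.ones(len(samples))
        burden[root] = 0
        members[root] = []
        rest = order
    parents[root] = None
    child_sum[root] = np.zeros(len(samples))

    def tree_depth(n: int) -> int:
        d = 0
        while parents[n] is not None:
            n = parents[n]
            d += 1
        return d

    for cl in rest:
        p_cl = cl.prevalence.to_numpy(float)
        best = None  # (depth, -slack) maximised
        report = []
        for cand in parents:
            contain = prev[cand] - p_cl + epsilon
            capacity = prev[cand] - child_sum[cand] - p_cl + epsilon
            if np.all(contain >= 0) and np.all(capacity >= 0):
                slack = float(np.sum(prev[cand] - p_cl))
                key = (tree_depth(cand), -slack)
                if best is None or key > best[0]:
                    best = (key, cand)
            else:
                bad = int(np.argmin(np.minimum(contain, capacity)))
                which = "containment" if contain[bad] < 0 else "capacity"
                report.append(f"node {cand}: {which} fails in sample {samples[bad]}")
        if best is None:
            raise PigeonholeInfeasibleError(
                f"cluster {cl.cluster_id} admits no parent; " + "; ".join(report)
            )
        parent = best[1]
        parents[cl.cluster_id] = parent
        prev[cl.cluster_id] = p_cl
        burden[cl.cluster_id] = cl.burden
        members[cl.cluster_id] = list(cl.members)
        child_sum[cl.cluster_id] = np.zeros(len(samples))
        child_sum[parent] = child_sum[parent] + p_cl

    prevalence = pd.DataFrame(
        np.stack([prev[n] for n in parents]), index=list(parents), columns=samples
    )
    return CloneTree(
        parents=parents,
        prevalence=prevalence,
        burden=burden,
        epsilon=epsilon,
        members=members,
    )
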