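"""Synthetic clone trees and noisy multi-sample read-count tables.

The generator emulates the data a multi-tissue lineage-tracing study
produces: an embryonic clone tree whose nodes carry per-sample cellular
prevalences obeying the pigeonhole constraint (in every sample, daughter
clones can never sum to more than their parent), mutation clusters assigned
to branches, germline variants at VAF ~= 0.5 in every tissue, binomially
sampled read counts at ~30-40x depth, and a low per-read miscall rate.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import VariantTable

#: parent must exceed the sum of its children by at least this much,
#: in every sample (strict pigeonhole margin, prevalence scale)
DOMINANCE_MARGIN = 0.02

# Separation requirements used when drawing "well separated" trees; they make
# the true tree the unique reconciliation of the true prevalences and keep
# clone profiles apart on the scale of binomial noise at ~40x depth.
_CROSSING_GAP = 0.10  # non-nested clones must cross by this much somewhere
_EDGE_GAP = 0.15  # parent must exceed child by this much in some sample
_DETECT_MIN = 0.15  # every clone reaches this prevalence in some sample
_UBIQUITY_CAP = 0.60  # non-root mean prevalence stays below this


class InvalidConfigError(ValueError):
    """Raised for a simulation configuration outside its documented ranges."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic patient.

    Defaults mirror a small multi-tissue WGS cohort: one tumour plus several
    normal tissues at ~40x coverage, a handful of embryonic clones with a
    few hundred mutations per branch, and a low sequencing miscall rate.
    """

    n_samples: int = 5
    n_clones: int = 4
    burden_range: tuple[int, int] = (150, 300)
    depth_mean: float = 40.0
    error_rate: float = 1e-3
    n_germline: int = 500
    sex: str = "female"
    seed: int = 0
    n_sex_sites: int = 0  # optional haploid chrX somatic sites (male only)

    def __post_init__(self):
        if self.n_samples < 1 or self.n_clones < 1:
            raise InvalidConfigError("n_samples and n_clones must be >= 1")
        lo, hi = self.burden_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("burden_range must satisfy 0 < min <= max")
        if self.depth_mean <= 0:
            raise InvalidConfigError("depth_mean must be positive")
        if not 0.0 <= self.error_rate <= 0.01:
            raise InvalidConfigError("error_rate must lie in [0, 0.01]")
        if self.n_germline < 0 or self.n_sex_sites < 0:
            raise InvalidConfigError("site counts must be non-negative")
        if self.sex not in ("male", "female"):
            raise InvalidConfigError("sex must be 'male' or 'female'")
        if self.n_sex_sites and self.sex != "male":
            raise InvalidConfigError("haploid sex-chromosome sites require sex='male'")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i}" for i in range(self.n_samples)]


@dataclass
class TruthTree:
    """Ground-truth clonal structure behind one synthetic dataset.

    ``prevalence`` is nodes x samples (cell fractions in [0, 1]);
    ``assignment`` maps somatic mutation ids to the node whose branch
    carries them; ``germline_ids`` lists injected germline sites.
    """

    parents: dict[int, int | None]
    prevalence: pd.DataFrame
    assignment: pd.Series
    seed: int
    germline_ids: list[str] = field(default_factory=list)
    well_separated: bool = True

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

    @property
    def branch_burden(self) -> pd.Series:
        counts = self.assignment.value_counts()
        return counts.reindex(self.nodes, fill_value=0).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [[n, self.parents[n]] for n in self.nodes],
                "prevalence": {
                    str(n): {s: float(self.prevalence.loc[n, s]) for s in self.prevalence.columns}
                    for n in self.nodes
                },
                "assignment": {m: int(k) for m, k in self.assignment.items()},
                "germline_ids": list(self.germline_ids),
                "seed": self.seed,
                "well_separated": self.well_separated,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTree":
        d = json.loads(text)
        parents = {int(n): (None if p is None else int(p)) for n, p in d["nodes"]}
        prev = pd.DataFrame({int(n): v for n, v in d["prevalence"].items()}).T.sort_index()
        assignment = pd.Series(d["assignment"], dtype=int)
        assignment.index.name = "mutation_id"
        return cls(
            parents=parents,
            prevalence=prev,
            assignment=assignment,
            seed=int(d["seed"]),
            germline_ids=list(d["germline_ids"]),
            well_separated=bool(d.get("well_separated", True)),
        )


# ---------------------------------------------------------------------------
# truth generation


def _draw_topology(n_clones: int, rng: np.random.Generator) -> dict[int, int | None]:
    parents: dict[int, int | None] = {0: None}
    for i in range(1, n_clones):
        parents[i] = int(rng.integers(0, i))
    return parents


def _draw_prevalence(
    parents: dict[int, int | None], n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Recursive stick-breaking from the root down, one stick per sample.

    Every internal node must dominate the sum of its children by the
    margin in every sample, so each internal node carries a recursive
    minimum requirement (its margin plus its descendants' requirements)
    that is reserved before the remaining stick is split.
    """
    n = len(parents)
    children: dict[int, list[int]] = {k: [] for k in parents}
    for k, p in parents.items():
        if p is not None:
            children[p].append(k)

    need = {k: 0.0 for k in parents}
    for node in range(n - 1, -1, -1):  # ids are topological: parent < child
        if children[node]:
            need[node] = DOMINANCE_MARGIN + sum(need[c] for c in children[node])
    if need[0] > 1.0:
        raise InvalidConfigError(
            "tree too deep for the dominance margin: reduce n_clones"
        )

    prev = np.zeros((n, n_samples))
    prev[0] = 1.0
    for node in range(n):
        kids = children[node]
        if not kids:
            continue
        reserved = sum(need[c] for c in kids)
        for s in range(n_samples):
            budget = prev[node, s] - DOMINANCE_MARGIN  # >= reserved by recursion
            spare = max(budget - reserved, 0.0)
            total = spare * rng.uniform(0.35, 0.95)
            shares = rng.dirichlet(np.ones(len(kids)))
            for kid, w in zip(kids, shares):
                prev[kid, s] = need[kid] + total * w
    return prev


def _ancestors(parents: dict[int, int | None], node: int) -> set[int]:
    out = set()
    p = parents[node]
    while p is not None:
        out.add(p)
        p = parents[p]
    return out


def _well_separated(parents: dict[int, int | None], prev: np.ndarray) -> bool:
    """True when the tree is uniquely reconstructable from exact prevalences."""
    n = prev.shape[0]
    anc = {k: _ancestors(parents, k) for k in range(n)}
    for v in range(1, n):
        if prev[v].max() < _DETECT_MIN:
            return False
        if prev[v].mean() > _UBIQUITY_CAP:
            return False
        pa = parents[v]
        if (prev[pa] - prev[v]).max() < _EDGE_GAP:
            return False
        for u in range(n):
            if u == v or u in anc[v] or v in anc[u]:
                continue
            if (prev[v] - prev[u]).max() < _CROSSING_GAP:
                return False
    return True


def simulate_truth(config: SimulationConfig, max_tries: int = 500) -> TruthTree:
    """Draw a ground-truth clone tree with per-sample prevalences.

    The root is the ubiquitous embryonic lineage (prevalence 1 everywhere);
    every parent strictly dominates the sum of its children in every sample
    by at least :data:`DOMINANCE_MARGIN`. Prevalence draws are rejected
    until clone profiles are well separated (see module constants); if no
    separated draw is found the last margin-valid draw is kept and
    ``well_separated`` is set to False.
    """
    rng = np.random.default_rng(config.seed)
    parents = _draw_topology(config.n_clones, rng)
    prev = _draw_prevalence(parents, config.n_samples, rng)
    separated = _well_separated(parents, prev)
    tries = 0
    while not separated and tries < max_tries:
        tries += 1
        if tries % 50 == 0:  # occasionally try a different topology
            parents = _draw_topology(config.n_clones, rng)
        prev = _draw_prevalence(parents, config.n_samples, rng)
        separated = _well_separated(parents, prev)

    burdens = rng.integers(config.burden_range[0], config.burden_range[1] + 1, config.n_clones)
    labels, nodes = [], []
    m = 0
    for node in range(config.n_clones):
        for _ in range(int(burdens[node])):
            labels.append(f"m{m:06d}")
            nodes.append(node)
            m += 1
    assignment = pd.Series(nodes, index=pd.Index(labels, name="mutation_id"), dtype=int)
    prevalence = pd.DataFrame(prev, index=list(parents), columns=config.sample_ids)
    return TruthTree(
        parents=parents,
        prevalence=prevalence,
        assignment=assignment,
        seed=config.seed,
        well_separated=separated,
    )


# ---------------------------------------------------------------------------
# read counts


def _truncated_poisson(rng: np.random.Generator, mean: float, shape) -> np.ndarray:
    d = rng.poisson(mean, shape)
    d[d == 0] = 1  # clamp: depth of at least one read at every retained site
    return d


def simulate_counts(truth: TruthTree, config: SimulationConfig) -> VariantTable:
    """Sample a read-count table from the truth tree.

    Autosomal somatic mutations are heterozygous diploid: expected
    VAF = prevalence / 2. Per cell, depth ~ Poisson(depth_mean) clamped to
    >= 1 and alt ~ Binomial(depth, vaf * (1 - e) + (1 - vaf) * e) with ``e``
    the per-read miscall rate. Optional male chrX sites are haploid
    (half depth, VAF = prevalence).
    """
    rng = np.random.default_rng([config.seed, 1])
    ids = truth.assignment.index
    m = len(ids)
    n_x = min(config.n_sex_sites, m)
    prev = truth.prevalence.loc[truth.assignment.to_numpy(), :].to_numpy()

    depth = _truncated_poisson(rng, config.depth_mean, (m, config.n_samples))
    vaf = prev / 2.0
    if n_x:
        # the last n_x mutations sit on chrX of a male patient
        depth[m - n_x :] = _truncated_poisson(rng, config.depth_mean / 2.0, (n_x, config.n_samples))
        vaf[m - n_x :] = prev[m - n_x :]
    e = config.error_rate
    p = vaf * (1.0 - e) + (1.0 - vaf) * e
    alt = rng.binomial(depth, p)

    chroms = ["1"] * (m - n_x) + ["X"] * n_x
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(1, m + 1) * 10,
            "ref": "A",
            "alt": "T",
        },
        index=ids,
    )
    return VariantTable(
        sites,
        pd.DataFrame(alt, index=ids, columns=config.sample_ids),
        pd.DataFrame(depth, index=ids, columns=config.sample_ids),
    )


def inject_germline(
    table: VariantTable, truth: TruthTree, config: SimulationConfig
) -> VariantTable:
    """Append germline heterozygous sites (expected VAF 0.5 in every sample).

    The injected ids are recorded in ``truth.germline_ids`` so classifier
    output can be scored exactly.
    """
    if config.n_germline == 0:
        truth.germline_ids = []
        return table
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_germline
    ids = pd.Index([f"g{i:06d}" for i in range(n)], name="mutation_id")
    depth = _truncated_poisson(rng, config.depth_mean, (n, config.n_samples))
    alt = rng.binomial(depth, 0.5)
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 50_000_000 + np.arange(1, n + 1) * 10,
            "ref": "G",
            "alt": "C",
        },
        index=ids,
    )
    sites["chrom_class"] = "autosome"
    truth.germline_ids = list(ids)
    return VariantTable(
        pd.concat([table.sites, sites]),
        pd.concat([table.alt, pd.DataFrame(alt, index=ids, columns=table.samples)]),
        pd.concat([table.depth, pd.DataFrame(depth, index=ids, columns=table.samples)]),
    )


def simulate_dataset(config: SimulationConfig) -> tuple[TruthTree, VariantTable]:
    """Convenience wrapper: truth tree, somatic counts, injected germline."""
    truth = simulate_truth(config)
    table = simulate_counts(truth, config)
    table = inject_germline(table, truth, config)
    return truth, table
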