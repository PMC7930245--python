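"""End-to-end pipeline: filter -> presence -> cluster -> tree.

One patient per run. Every run writes a manifest recording the seed, a
hash of the full configuration and the artefact list, so identical config
and seed reproduce identical artefacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import gibbs_run, point_estimate
from .datatypes import SampleMeta, VariantTable
from .filters import LABEL_SOMATIC, FilterConfig, classify_germline_somatic, depth_filter
from .io import exclude_regions, read_bed
from .presence import call_presence, shared_mutation_counts
from .tree import build_tree

logger = logging.getLogger("somaclone")


class PipelineStageError(RuntimeError):
    """Wraps a stage failure; partial artefacts written so far are kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, validated against documented ranges."""

    seed: int = 0
    # germline/somatic + depth filters
    q_cutoff: float = 1e-5
    depth_min: float = 15.0
    depth_max: float = 50.0
    germline_vaf_null: float = 0.5
    sex_halving: bool = True
    matched_only: bool = False
    consistency: str = "all"
    # presence model
    presence_threshold: float = 1e-3
    vaf_fit_max: float = 0.1
    # DP clustering
    n_iter: int = 2000
    burn_in: int = 500
    alpha_shape: float = 1.0
    alpha_rate: float = 1.0
    fixed_alpha: float | None = None
    min_cluster_size: int = 5
    write_coassignment: bool = False
    # tree reconciliation
    epsilon: float = 0.05
    exclude_bed: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        self.filter_config()  # range checks delegated
        if not 0.0 < self.presence_threshold < 1.0:
            raise ValueError("presence_threshold must lie in (0, 1)")
        if not 0.0 < self.vaf_fit_max <= 0.5:
            raise ValueError("vaf_fit_max must lie in (0, 0.5]")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.alpha_shape <= 0 or self.alpha_rate <= 0:
            raise ValueError("alpha prior parameters must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            q_cutoff=self.q_cutoff,
            depth_min=self.depth_min,
            depth_max=self.depth_max,
            germline_vaf_null=self.germline_vaf_null,
            sex_halving=self.sex_halving,
            matched_only=self.matched_only,
            consistency=self.consistency,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    artefacts: dict[str, Path]
    filtered: VariantTable
    audit: pd.DataFrame
    presence: "object"
    clusters: list
    tree: "object"
    report: dict


def _write_presence(call, outdir: Path) -> dict[str, Path]:
    paths = {
        "presence_matrix": outdir / "presence.tsv",
        "presence_pvalues": outdir / "presence_pvalues.tsv",
    }
    call.present.astype(int).to_csv(paths["presence_matrix"], sep="\t")
    call.p_values.to_csv(paths["presence_pvalues"], sep="\t", float_format="%.6g")
    return paths


def _write_clusters(clusters, trace, outdir: Path, write_co: bool) -> dict[str, Path]:
    paths = {}
    rows = []
    for cl in clusters:
        for m in cl.members:
            rows.append((m, cl.cluster_id))
    assign = pd.DataFrame(rows, columns=["mutation_id", "cluster_id"]).sort_values(
        "mutation_id"
    )
    paths["assignments"] = outdir / "assignments.tsv"
    assign.to_csv(paths["assignments"], sep="\t", index=False)

    summary = []
    for cl in clusters:
        row = {"cluster_id": cl.cluster_id, "burden": cl.burden}
        for s, v in cl.theta_hat.items():
            row[f"theta:{s}"] = round(float(v), 6)
        for s, v in cl.prevalence.items():
            row[f"prevalence:{s}"] = round(float(v), 6)
        summary.append(row)
    paths["clusters"] = outdir / "clusters.tsv"
    pd.DataFrame(summary).to_csv(paths["clusters"], sep="\t", index=False)

    if write_co:
        co = trace.co_assignment()
        paths["coassignment"] = outdir / "coassignment.mtx"
        arr = co.to_numpy()
        nz = np.argwhere(arr > 0)
        with open(paths["coassignment"], "w") as fh:
            fh.write("%%MatrixMarket matrix coordinate real symmetric\n")
            fh.write(f"{arr.shape[0]} {arr.shape[1]} {len(nz)}\n")
            for i, j in nz:
                if i >= j:
                    fh.write(f"{i + 1} {j + 1} {arr[i, j]:.6g}\n")
    return paths


def run_pipeline(
    table: VariantTable,
    samples: SampleMeta,
    config: PipelineConfig,
    outdir,
) -> PipelineResult:
    """Execute filter -> presence -> cluster -> tree and write the bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    artefacts: dict[str, Path] = {"log": log_path}
    fconf = config.filter_config()

    try:
        stage = "filter"
        if config.exclude_bed:
            table = exclude_regions(table, read_bed(config.exclude_bed))
        filtered, removal_log = depth_filter(table, samples, fconf)
        cls = classify_germline_somatic(filtered, samples, fconf)
        cls["filter_rule"] = "pass"
        audit = pd.concat(
            [
                cls,
                removal_log.assign(label="depth_filtered").rename(
                    columns={"rule": "filter_rule"}
                ),
            ]
        ).loc[:, ["p", "q", "label", "filter_rule"]]
        somatic = filtered.subset(cls["label"] == LABEL_SOMATIC)
        logger.info(
            "filter: %d sites in, %d depth-filtered, %d somatic",
            table.n_sites,
            len(removal_log),
            somatic.n_sites,
        )
        from .io import write_variant_tsv

        artefacts["filtered_table"] = outdir / "somatic.tsv"
        write_variant_tsv(somatic, artefacts["filtered_table"])
        artefacts["audit"] = outdir / "audit.tsv"
        audit.to_csv(artefacts["audit"], sep="\t", float_format="%.6g")

        stage = "presence"
        presence = call_presence(
            somatic, threshold=config.presence_threshold, vaf_fit_max=config.vaf_fit_max
        )
        artefacts.update(_write_presence(presence, outdir))
        shared = shared_mutation_counts(presence)
        logger.info("presence: %d present calls", int(presence.present.to_numpy().sum()))

        stage = "cluster"
        trace = gibbs_run(
            somatic,
            presence,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=config.seed,
            alpha_prior=(config.alpha_shape, config.alpha_rate),
            fixed_alpha=config.fixed_alpha,
        )
        clusters = point_estimate(trace, min_cluster_size=config.min_cluster_size)
        artefacts.update(
            _write_clusters(clusters, trace, outdir, config.write_coassignment)
        )
        logger.info("cluster: %d clusters", len(clusters))

        stage = "tree"
        tree = build_tree(clusters, epsilon=config.epsilon)
        artefacts["tree"] = outdir / "tree.json"
        artefacts["tree"].write_text(tree.to_json())
        artefacts["tree_newick"] = outdir / "tree.nwk"
        artefacts["tree_newick"].write_text(tree.to_newick() + "\n")
        artefacts["tree_dot"] = outdir / "tree.dot"
        artefacts["tree_dot"].write_text(tree.to_dot() + "\n")

        stage = "report"
        report = {
            "n_input_sites": int(table.n_sites),
            "n_depth_filtered": int(len(removal_log)),
            "n_somatic": int(somatic.n_sites),
            "n_clusters": len(clusters),
            "shared_mutation_counts": {
                a: {b: int(shared.loc[a, b]) for b in shared.columns}
                for a in shared.index
            },
            "clone_tree_nodes": len(tree.nodes),
        }
        artefacts["report"] = outdir / "report.json"
        artefacts["report"].write_text(json.dumps(report, indent=1, sort_keys=True))

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "artefacts": {k: str(p.name) for k, p in sorted(artefacts.items())},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        artefacts["manifest"] = outdir / "manifest.json"
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, e) from e
    finally:
        logger.removeHandler(handler)
        handler.close()

    return PipelineResult(
        outdir=outdir,
        artefacts=artefacts,
        filtered=somatic,
        audit=audit,
        presence=presence,
        clusters=clusters,
        tree=tree,
        report=report,
    )
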