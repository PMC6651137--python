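"""End-to-end orchestration: load → layers → diffuse → module → clusters.

A single config (YAML-friendly mapping) drives every stage; one
top-level seed derives the sub-seeds of all stochastic stages, so a
re-run with the same config is bit-identical. Each stage writes its
outputs as TSV and a manifest records parameters and content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import communities as comm
from . import diffusion as diff
from . import layers as lay
from . import module_detection as mod
from .errors import ValidationError
from .interactome import load_edge_list, normalize

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("netprop")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (CLI flags override config files)."""

    edges: str = ""
    gene_lists: str = ""
    gmt: str | None = None
    out_dir: str = "netprop_out"
    min_score: int = 700
    layer_order: Sequence[str] | None = None
    alpha: float = 0.7
    tol: float = 1e-6
    max_iter: int = 10_000
    m_neighbors: int = 3
    n_perm: int = 1000
    statistic: str = "d"
    k_grid: Sequence[int] = field(default_factory=lambda: list(mod.DEFAULT_K_GRID))
    R: int = 999
    alpha_nr: float = 0.01
    null: str = "degree_matched"
    module_rule: str = "max_z"
    community_methods: Sequence[str] = field(default_factory=lambda: list(comm.METHODS))
    universe: str = "interactome"  # or "gmt"
    seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage sub-seed derived from the top-level seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_scores(result: diff.DiffusionResult, path: Path) -> None:
    cols = {"gene": result.genes}
    for j, name in enumerate(result.layer_names):
        cols[f"xss_{name}"] = result.Xss[:, j]
    for j, name in enumerate(result.layer_names):
        cols[f"xstar_{name}"] = result.Xstar[:, j]
    for j, name in enumerate(result.layer_names):
        cols[f"ystar_{name}"] = result.Y[:, j]
    cols["d"] = result.d
    if result.p is not None:
        cols["p"] = result.p
    df = pd.DataFrame(cols)
    order = np.argsort(-df["d"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs + manifest, return result bundle.

    A stage failure aborts with the stage named; outputs of completed
    stages are retained on disk. With ``n_perm = 0`` the scores table
    carries no p column and core-extension selection is unavailable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    bundle: dict = {"config": config}
    t0 = time.time()

    current = {"stage": "init"}

    def _stage(name):
        current["stage"] = name
        log.info("[%s] starting (t=%.1fs)", name, time.time() - t0)

    try:
        _stage("load")
        net = load_edge_list(config.edges, min_score=config.min_score)
        W = normalize(net)
        outputs["network"] = out / "network.tsv"
        net.write_edge_list(outputs["network"])
        bundle["net"] = net

        _stage("layers")
        layers = lay.read_gene_lists(config.gene_lists)
        layers, report = lay.restrict_to_network(layers, net)
        X0 = lay.build_matrix(layers, net, layer_order=config.layer_order)
        outputs["layer_report"] = out / "layer_report.tsv"
        report.to_csv(outputs["layer_report"], sep="\t", index=False)
        bundle["layers"], bundle["layer_report"], bundle["X0"] = layers, report, X0

        _stage("diffuse")
        result = diff.score_genes(
            net, W, X0,
            alpha=config.alpha, tol=config.tol, max_iter=config.max_iter,
            m=config.m_neighbors, n_perm=config.n_perm,
            seed=config.stage_seed("permutation"), statistic=config.statistic,
        )
        outputs["scores"] = out / "scores.tsv"
        _write_scores(result, outputs["scores"])
        bundle["result"] = result

        _stage("module")
        ranking = mod.rank_genes(result, statistic=config.statistic)
        k_grid = [k for k in config.k_grid if k <= net.n_nodes]
        per_k = mod.network_resampling(
            net, ranking, k_grid=k_grid, R=config.R,
            seed=config.stage_seed("resampling"), null=config.null,
            W=W, X0=X0, alpha=config.alpha, statistic=config.statistic,
            m=config.m_neighbors,
        )
        module = mod.extract_module(
            net, ranking, per_k, alpha_nr=config.alpha_nr, rule=config.module_rule
        )
        outputs["module_scan"] = out / "module_scan.tsv"
        per_k.to_csv(outputs["module_scan"], sep="\t", index=False)
        outputs["module"] = out / "module.tsv"
        rank_of = {g: r for r, g in enumerate(ranking.genes, start=1)}
        pd.DataFrame(
            {
                "gene": module.members,
                "rank": [rank_of[g] for g in module.members],
                "d": [result.d[net.index[g]] for g in module.members],
            }
        ).to_csv(outputs["module"], sep="\t", index=False, float_format="%.10g")
        bundle["ranking"], bundle["module"] = ranking, module

        _stage("communities")
        lcc = mod.largest_component(module)
        partition = None
        if len(lcc) >= 2:
            sub = net.to_networkx().subgraph(lcc).copy()
            parts = comm.detect_communities(
                sub, methods=config.community_methods,
                seed=config.stage_seed("communities"),
            )
            partition = comm.best_partition(parts)
            outputs["partition"] = out / "partition.tsv"
            pd.DataFrame(
                sorted(partition.membership.items()), columns=["gene", "cluster"]
            ).to_csv(outputs["partition"], sep="\t", index=False)
            bundle["partitions"] = parts
        bundle["partition"] = partition

        _stage("enrich")
        if partition is not None:
            # per-cluster evidence-type enrichment over the module
            rows = []
            module_set = set(module.members)
            clusters = partition.clusters()
            for label, members in sorted(clusters.items()):
                for layer in layers:
                    ratio = comm.evidence_enrichment(
                        members, layer.genes & module_set, lcc
                    )
                    rows.append((label, layer.name, ratio))
            evidence = pd.DataFrame(rows, columns=["cluster", "layer", "ratio"])
            outputs["evidence_enrichment"] = out / "evidence_enrichment.tsv"
            evidence.to_csv(
                outputs["evidence_enrichment"], sep="\t", index=False,
                float_format="%.6g",
            )
            bundle["evidence_enrichment"] = evidence
            if config.gmt:
                gene_sets = comm.read_gmt(config.gmt)
                if config.universe == "interactome":
                    universe = net.n_nodes
                elif config.universe == "gmt":
                    universe = len(set().union(*gene_sets.values()))
                else:
                    raise ValidationError(f"unknown universe rule {config.universe!r}")
                enrich = comm.pathway_enrichment(partition, gene_sets, universe)
                outputs["pathway_enrichment"] = out / "pathway_enrichment.tsv"
                enrich.to_csv(
                    outputs["pathway_enrichment"], sep="\t", index=False,
                    float_format="%.6g",
                )
                bundle["pathway_enrichment"] = enrich
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {current['stage']!r} failed: {exc}"
        ) from exc

    log.info("pipeline finished in %.1fs", time.time() - t0)
    manifest = {
        "parameters": {
            k: (list(v) if isinstance(v, (tuple,)) else v)
            for k, v in asdict(config).items()
        },
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
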