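"""Topological clustering of a gene module and per-cluster enrichment.

The module's largest connected component is partitioned by several
community-detection families (greedy modularity optimization, edge
betweenness removal, label propagation, leading eigenvector, short
random walks); every partition is scored with the Newman modularity

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)

and the best partition is carried forward. Clusters are then tested
for over-representation of pathway gene sets (hypergeometric upper
tail, BH-adjusted q-values) and for per-layer evidence enrichment.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import pandas as pd

from .errors import ValidationError
from .stats import bh_adjust, hypergeom_upper_tail

__all__ = [
    "Partition",
    "METHODS",
    "detect_communities",
    "newman_modularity",
    "best_partition",
    "pathway_enrichment",
    "evidence_enrichment",
    "read_gmt",
    "write_gmt",
]

METHODS = (
    "greedy",
    "edge_betweenness",
    "label_propagation",
    "leading_eigenvector",
    "walktrap",
)

_STOCHASTIC = {"label_propagation"}


@dataclass(frozen=True)
class Partition:
    """A clustering of the module genes with its modularity score."""

    membership: Mapping[str, int]
    method: str
    Q: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.membership.values()))

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, label in self.membership.items():
            out.setdefault(label, set()).add(gene)
        return out


def newman_modularity(graph: nx.Graph, membership: Mapping[str, int]) -> float:
    """Newman modularity Q of a node partition.

    Edgeless graphs score 0 by convention (the 1/2m factor is guarded).
    """
    missing = set(graph.nodes) - set(membership)
    if missing:
        raise ValidationError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    deg = dict(graph.degree())
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for node in graph.nodes:
        c = membership[node]
        d_c[c] = d_c.get(c, 0) + deg[node]
    for a, b in graph.edges:
        if membership[a] == membership[b]:
            c = membership[a]
            e_c[c] = e_c.get(c, 0) + 1
    return sum(
        e_c.get(c, 0) / m - (d_c[c] / (2 * m)) ** 2 for c in d_c
    )


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(graph.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    edges = [(idx[a], idx[b]) for a, b in graph.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def detect_communities(
    graph: nx.Graph,
    methods: Sequence[str] = METHODS,
    seed: int | None = None,
) -> list[Partition]:
    """Run the requested community-detection families on a graph.

    Each returned Partition is scored with :func:`newman_modularity`.
    Stochastic methods require ``seed``; deterministic ones ignore it.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown method(s) {sorted(unknown)}; choose from {METHODS}")
    if _STOCHASTIC & set(methods) and seed is None:
        raise ValidationError("a seed is required for stochastic methods")
    g, nodes = _to_igraph(graph)
    out = []
    for method in methods:
        if method in _STOCHASTIC:
            ig.set_random_number_generator(random.Random(seed))
        if method == "greedy":
            clu = g.community_fastgreedy().as_clustering()
        elif method == "edge_betweenness":
            clu = g.community_edge_betweenness().as_clustering()
        elif method == "label_propagation":
            clu = g.community_label_propagation()
        elif method == "leading_eigenvector":
            clu = g.community_leading_eigenvector()
        elif method == "walktrap":
            clu = g.community_walktrap().as_clustering()
        membership = {nodes[i]: c for i, c in enumerate(clu.membership)}
        out.append(
            Partition(
                membership=membership,
                method=method,
                Q=newman_modularity(graph, membership),
            )
        )
    return out


def best_partition(partitions: Sequence[Partition]) -> Partition:
    """Maximum-Q partition; ties prefer fewer clusters, then input order."""
    if not partitions:
        raise ValidationError("no partitions supplied")
    return max(
        enumerate(partitions),
        key=lambda t: (t[1].Q, -t[1].n_clusters, -t[0]),
    )[1]


def pathway_enrichment(
    partition: Partition,
    gene_sets: Mapping[str, Iterable[str]],
    universe: int,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each cluster.

    Returns one row per (cluster, gene set) with the overlap count, the
    nominal p and the BH-adjusted q computed over the whole table.
    """
    if not gene_sets:
        raise ValidationError("empty gene-set collection")
    sets = {name: set(g) for name, g in gene_sets.items()}
    too_big = [n for n, s in sets.items() if len(s) > universe]
    if too_big:
        raise ValidationError(f"gene set(s) larger than universe: {too_big[:5]}")
    rows = []
    for label, members in sorted(partition.clusters().items()):
        for name in sorted(sets):
            s = sets[name]
            k = len(members & s)
            p = hypergeom_upper_tail(universe, len(s), len(members), k)
            rows.append((label, name, len(members), len(s), k, p))
    df = pd.DataFrame(
        rows,
        columns=["cluster", "gene_set", "cluster_size", "set_size", "overlap", "p"],
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def evidence_enrichment(
    cluster: Iterable[str],
    layer_support: Iterable[str],
    module: Iterable[str],
) -> float:
    """Ratio of within-cluster to within-module evidence support.

    (|cluster ∩ support| / |cluster|) / (|module ∩ support| / |module|);
    1 means the cluster carries the same proportion of supported genes
    as the whole module. Undefined (NaN) when the module has no
    supported gene.
    """
    cluster, support, module = set(cluster), set(layer_support), set(module)
    if not cluster <= module:
        raise ValidationError("cluster must be a subset of the module")
    module_frac = len(module & support) / len(module)
    if module_frac == 0:
        return float("nan")
    return (len(cluster & support) / len(cluster)) / module_frac


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name, description, then tab-separated genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one gene"
                )
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
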