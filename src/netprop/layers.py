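"""Assemble per-layer evidence gene sets into the diffusion seed matrix.

Each omics layer (by default G = genomics, E = epigenomics,
T = transcriptomics) contributes a major-tier and a minor-tier gene
list. Tiers encode the strength of disease association and map to seed
values 1 (major), 0.5 (minor) and 0 (no evidence) in the genes-by-layers
matrix X0 consumed by diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .interactome import Interactome

__all__ = [
    "EvidenceLayer",
    "EvidenceMatrix",
    "read_gene_lists",
    "write_gene_lists",
    "restrict_to_network",
    "build_matrix",
]

MAJOR = 1.0
MINOR = 0.5


@dataclass
class EvidenceLayer:
    """One omics evidence source with major and minor gene tiers.

    A gene listed in both tiers is kept as major (major wins).
    """

    name: str
    major: set[str] = field(default_factory=set)
    minor: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.minor = set(self.minor) - set(self.major)
        self.major = set(self.major)

    @property
    def genes(self) -> set[str]:
        return self.major | self.minor


@dataclass(frozen=True)
class EvidenceMatrix:
    """Genes-by-layers seed matrix X0 with entries in {0, 0.5, 1}.

    Row order matches the interactome node order; column order is the
    configured layer order.
    """

    genes: tuple[str, ...]
    layer_names: tuple[str, ...]
    X0: np.ndarray

    def column_sums(self) -> np.ndarray:
        return self.X0.sum(axis=0)


def read_gene_lists(path: str | Path) -> list[EvidenceLayer]:
    """Parse a (gene, layer, tier) TSV into one EvidenceLayer per layer.

    Tier must be ``major`` or ``minor``; duplicates are removed and a
    gene appearing in both tiers of a layer is kept as major. Layers are
    returned in order of first appearance.

    Raises
    ------
    ValidationError
        On an unknown tier value or an empty file.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "layer", "tier"],
        dtype=str, comment="#", skip_blank_lines=True,
    )
    # tolerate an optional header row
    if len(df) and df.iloc[0].tolist() == ["gene", "layer", "tier"]:
        df = df.iloc[1:]
    if df.empty:
        raise ValidationError(f"{path}: no gene-list rows found")
    bad = set(df["tier"]) - {"major", "minor"}
    if bad:
        raise ValidationError(
            f"{path}: unknown tier value(s) {sorted(bad)}; expected major/minor"
        )
    layers: dict[str, dict[str, set]] = {}
    for name in df["layer"]:
        layers.setdefault(name, {"major": set(), "minor": set()})
    for gene, layer, tier in df.itertuples(index=False):
        layers[layer][tier].add(gene)
    return [
        EvidenceLayer(name=n, major=d["major"], minor=d["minor"])
        for n, d in layers.items()
    ]


def write_gene_lists(layers: Sequence[EvidenceLayer], path: str | Path) -> None:
    """Serialize layers back to the (gene, layer, tier) TSV format."""
    with open(path, "w") as fh:
        for layer in layers:
            for gene in sorted(layer.major):
                fh.write(f"{gene}\t{layer.name}\tmajor\n")
            for gene in sorted(layer.minor):
                fh.write(f"{gene}\t{layer.name}\tminor\n")


def restrict_to_network(
    layers: Sequence[EvidenceLayer], net: Interactome
) -> tuple[list[EvidenceLayer], pd.DataFrame]:
    """Drop genes absent from the interactome; report initial vs selected.

    The report mirrors the usual dataset-summary layout: one row per
    layer/tier with the count before and after network restriction.
    """
    kept: list[EvidenceLayer] = []
    rows = []
    for layer in layers:
        major = {g for g in layer.major if g in net}
        minor = {g for g in layer.minor if g in net}
        kept.append(EvidenceLayer(name=layer.name, major=major, minor=minor))
        rows.append((layer.name, "major", len(layer.major), len(major)))
        rows.append((layer.name, "minor", len(layer.minor), len(minor)))
    report = pd.DataFrame(rows, columns=["layer", "tier", "initial", "selected"])
    return kept, report


def build_matrix(
    layers: Sequence[EvidenceLayer],
    net: Interactome,
    layer_order: Sequence[str] | None = None,
) -> EvidenceMatrix:
    """Encode layers as the seed matrix X0 over the interactome genes.

    X0[i, j] is 1 if gene i is major in layer j, 0.5 if minor, else 0.
    Layers should already be restricted to the network; off-network
    genes are ignored here.
    """
    by_name = {l.name: l for l in layers}
    if layer_order is None:
        names = [l.name for l in layers]
    else:
        missing = set(layer_order) - set(by_name)
        if missing:
            raise ValidationError(f"layer_order names absent from input: {missing}")
        names = list(layer_order)
    X0 = np.zeros((net.n_nodes, len(names)))
    for j, name in enumerate(names):
        layer = by_name[name]
        for gene in layer.major:
            i = net.index.get(gene)
            if i is not None:
                X0[i, j] = MAJOR
        for gene in layer.minor:
            i = net.index.get(gene)
            if i is not None:
                X0[i, j] = MINOR
    return EvidenceMatrix(genes=net.nodes, layer_names=tuple(names), X0=X0)
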