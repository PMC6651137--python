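"""Load, clean and normalize the gene–gene interaction network.

The interactome is an undirected graph over opaque gene identifiers with
STRING-style integer confidence scores (0–1000). Scores are used only to
threshold edges; downstream diffusion runs on the unweighted 0/1
adjacency. Duplicate records of the same unordered pair are collapsed to
the highest-scoring one before thresholding, self-loops are dropped, and
each retained pair is stored once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import networkx as nx
import scipy.sparse as sp

from .errors import EmptyNetworkError, LookupError_, ParseError, ValidationError

__all__ = ["Interactome", "NormalizedOperator", "load_edge_list", "normalize"]


@dataclass(frozen=True)
class Interactome:
    """Undirected weighted gene graph with a 0/1 sparse adjacency.

    Attributes
    ----------
    nodes
        Sorted gene identifiers; row/column order of ``adjacency``.
    scores
        Mapping from unordered pair (a, b) with a < b to the integer
        confidence score of the retained record.
    adjacency
        Sparse symmetric CSR matrix with 0/1 entries, no diagonal.
    """

    nodes: tuple[str, ...]
    scores: Mapping[tuple[str, str], int]
    adjacency: sp.csr_matrix
    index: Mapping[str, int] = field(repr=False, default=None)

    def __post_init__(self):
        if self.index is None:
            object.__setattr__(
                self, "index", {g: i for i, g in enumerate(self.nodes)}
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.scores)

    @property
    def degree(self) -> np.ndarray:
        """Per-node integer degree (row sums of the adjacency)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def neighbors(self, gene: str) -> set[str]:
        """Direct interaction partners of ``gene`` (adjacency row support)."""
        if gene not in self.index:
            raise LookupError_(f"gene {gene!r} is not in the network")
        i = self.index[gene]
        row = self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]
        return {self.nodes[j] for j in row}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, s) for (a, b), s in self.scores.items())
        return g

    def write_edge_list(self, path: str | Path, header: bool = True) -> None:
        """Serialize as a sorted three-column TSV (nodeA, nodeB, score)."""
        with open(path, "w") as fh:
            if header:
                fh.write("nodeA\tnodeB\tscore\n")
            for a, b in sorted(self.scores):
                fh.write(f"{a}\t{b}\t{self.scores[(a, b)]}\n")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "Interactome":
        """Build from (a, b, score) triples, keeping max score per pair.

        ``extra_nodes`` lets callers retain isolated genes (zero rows in
        the adjacency) so that gene indexing stays stable across layers.
        """
        scores: dict[tuple[str, str], int] = {}
        for a, b, s in edges:
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key not in scores or s > scores[key]:
                scores[key] = int(s)
        nodes = set(extra_nodes)
        for a, b in scores:
            nodes.add(a)
            nodes.add(b)
        ordered = tuple(sorted(nodes))
        idx = {g: i for i, g in enumerate(ordered)}
        n = len(ordered)
        if scores:
            rows, cols = [], []
            for a, b in scores:
                i, j = idx[a], idx[b]
                rows += [i, j]
                cols += [j, i]
            data = np.ones(len(rows), dtype=float)
            adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        else:
            adj = sp.csr_matrix((n, n))
        return cls(nodes=ordered, scores=scores, adjacency=adj, index=idx)


@dataclass(frozen=True)
class NormalizedOperator:
    """Symmetrically normalized adjacency W = D^{-1/2} A D^{-1/2}.

    Rows and columns of isolated nodes are all-zero; the spectral radius
    of W is at most 1, which makes the diffusion resolvent (I - aW)
    nonsingular for any a in (0, 1).
    """

    nodes: tuple[str, ...]
    W: sp.csr_matrix


def load_edge_list(
    path: str | Path,
    min_score: int = 700,
    header: str | bool = "auto",
) -> Interactome:
    """Read a STRING-style TSV edge list and apply cleaning rules.

    Records of the same unordered pair are first collapsed to the
    highest score, then edges below ``min_score`` and self-loops are
    dropped. The node set is the set of endpoints of retained edges.

    Parameters
    ----------
    min_score
        Minimum confidence score on the STRING 0–1000 scale.
    header
        ``True``/``False`` to force, or ``"auto"`` to skip a first line
        whose third field is not an integer.

    Raises
    ------
    ParseError
        On a malformed line (names the offending line number).
    EmptyNetworkError
        If no edge survives filtering.
    """
    if not 0 <= min_score <= 1000:
        raise ValidationError(f"min_score must be in [0, 1000], got {min_score}")
    triples: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b, raw = fields
            try:
                s = int(raw)
            except ValueError:
                if lineno == 1 and header in ("auto", True):
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: score {raw!r} is not an integer"
                ) from None
            if lineno == 1 and header is True:
                continue
            triples.append((a, b, s))
    # collapse duplicates to the max score, then threshold
    collapsed: dict[tuple[str, str], int] = {}
    for a, b, s in triples:
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in collapsed or s > collapsed[key]:
            collapsed[key] = s
    kept = [(a, b, s) for (a, b), s in collapsed.items() if s >= min_score]
    if not kept:
        raise EmptyNetworkError(
            f"{path}: no edge with score >= {min_score} remains after filtering"
        )
    return Interactome.from_edges(kept)


def normalize(net: Interactome) -> NormalizedOperator:
    """Symmetric normalization W_ij = A_ij / sqrt(d_i d_j).

    Entries touching an isolated node are zero by convention, so such
    genes receive only the (1 - alpha) X0 term under diffusion.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot normalize an empty network")
    d = net.degree.astype(float)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    D = sp.diags(inv_sqrt)
    W = (D @ net.adjacency @ D).tocsr()
    return NormalizedOperator(nodes=net.nodes, W=W)
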