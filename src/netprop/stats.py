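"""Hypergeometric overlap and neighbor-enrichment statistics.

All enrichment questions in the pipeline reduce to the upper tail of a
hypergeometric distribution: given a universe of N genes containing K
"successes", what is the probability of seeing at least k successes in
n draws without replacement? The universe defaults to the interactome
size throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .interactome import Interactome

__all__ = [
    "OverlapTest",
    "NeighborEnrichment",
    "hypergeom_upper_tail",
    "overlap_test",
    "neighbor_enrichment",
    "bh_adjust",
]


@dataclass(frozen=True)
class OverlapTest:
    """Significance of the overlap between two gene sets.

    ``expected`` is |A||B|/|U| and ``p_upper`` the exact probability of
    an overlap at least as large under random draws from the universe.
    """

    size_a: int
    size_b: int
    universe: int
    overlap: int
    expected: float
    p_upper: float


@dataclass(frozen=True)
class NeighborEnrichment:
    """Enrichment of one gene's interactors in a core gene set."""

    gene: str
    n_interactors: int
    n_core_interactors: int
    core_size: int
    universe: int
    p_upper: float


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Population N, K successes, n draws. Computed via the stable
    survival function; k = 0 covers the whole support and returns 1.
    """
    if not (0 <= K <= N):
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValidationError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> OverlapTest:
    """Upper-tail test of |A ∩ B| against random sets of the same sizes."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValidationError(
            f"set sizes ({len(a)}, {len(b)}) exceed the universe {universe_size}"
        )
    k = len(a & b)
    return OverlapTest(
        size_a=len(a),
        size_b=len(b),
        universe=universe_size,
        overlap=k,
        expected=len(a) * len(b) / universe_size,
        p_upper=hypergeom_upper_tail(universe_size, len(a), len(b), k),
    )


def neighbor_enrichment(
    net: Interactome, gene: str, core: Iterable[str]
) -> NeighborEnrichment:
    """Is ``gene``'s interaction neighborhood enriched in core genes?

    Draws = the gene's degree, successes = core set size, population =
    interactome size. The tested gene is excluded from neither the
    population nor the successes.
    """
    core = set(core)
    nbrs = net.neighbors(gene)  # raises on unknown gene
    k = len(nbrs & core)
    return NeighborEnrichment(
        gene=gene,
        n_interactors=len(nbrs),
        n_core_interactors=k,
        core_size=len(core),
        universe=net.n_nodes,
        p_upper=hypergeom_upper_tail(net.n_nodes, len(core), len(nbrs), k),
    )


def bh_adjust(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    ``method="bonferroni"`` gives the strict family-wise variant
    instead. Input p-values must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]
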