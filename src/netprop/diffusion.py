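"""Network-diffusion scoring of genes from multi-layer evidence.

Seed scores X0 (genes x layers, entries in {0, 0.5, 1}) are propagated
over the symmetrically normalized interactome W by iterating

    X_{t+1} = alpha * W @ X_t + (1 - alpha) * X0

to its fixed point Xss, equivalently the resolvent solve
(I - alpha W) Xss = (1 - alpha) X0. The mixing parameter alpha in (0, 1)
weights network smoothing against fidelity to the seeds; the default
0.7 favors diffusion while keeping seed identity recoverable.

From Xss, each column is rescaled by its maximum (X*), each gene gets a
neighborhood term y*_ij = mean of the top-m normalized scores among its
direct neighbors in layer j, and the composite score is

    d_i = (sum_j x*_ij) * (sum_j y*_ij),

so a high-scoring gene must both carry or receive evidence itself and
sit next to high-scoring neighbors. Significance is assessed by
permuting whole rows of X0 (a gene's multi-layer profile travels as a
unit) and recomputing the full score, with the add-one empirical
p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, ValidationError
from .interactome import Interactome, NormalizedOperator
from .layers import EvidenceMatrix

__all__ = [
    "DiffusionResult",
    "diffuse",
    "diffuse_closed_form",
    "normalize_columns",
    "top_neighbor_means",
    "composite_score",
    "permutation_pvalues",
    "select_core_extension",
    "score_genes",
]

DEFAULT_ALPHA = 0.7
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000

# above this node count the permutation engine falls back from a dense
# precomputed resolvent to per-permutation iterative solves
_DENSE_RESOLVENT_LIMIT = 4000


@dataclass
class DiffusionResult:
    """Steady-state, normalized and composite diffusion scores.

    Attributes
    ----------
    Xss, Xstar, Y
        Genes-by-layers steady state, column-max-normalized scores, and
        top-neighbor mean scores.
    d
        Per-gene composite score (sum of x* times sum of y*).
    p
        Per-gene empirical p-values, present when permutations were run.
    statistic
        Which statistic the p-values refer to ("d" or "xss").
    """

    genes: tuple[str, ...]
    layer_names: tuple[str, ...]
    Xss: np.ndarray
    Xstar: np.ndarray
    Y: np.ndarray
    d: np.ndarray
    alpha: float
    iterations: int
    residual: float
    p: np.ndarray | None = None
    statistic: str | None = None

    def scores(self, statistic: str = "d") -> np.ndarray:
        if statistic == "d":
            return self.d
        if statistic == "xss":
            return self.Xss.sum(axis=1)
        raise ValidationError(f"unknown statistic {statistic!r}")


def _as_W(W) -> sp.csr_matrix:
    return W.W if isinstance(W, NormalizedOperator) else sp.csr_matrix(W)


def _as_X0(X0) -> np.ndarray:
    arr = X0.X0 if isinstance(X0, EvidenceMatrix) else np.asarray(X0, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def diffuse(
    W,
    X0,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    return_info: bool = False,
):
    """Iterate the diffusion update to its steady state.

    Stops when the max-norm change between successive iterates drops
    below ``tol``. Raises :class:`ConvergenceError` (carrying the last
    residual) if ``max_iter`` is reached first — for alpha close to 1
    prefer :func:`diffuse_closed_form`.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if tol <= 0:
        raise ValidationError(f"tol must be positive, got {tol}")
    Wm = _as_W(W)
    X = _as_X0(X0)
    Xt = X.copy()
    for it in range(1, max_iter + 1):
        Xn = alpha * (Wm @ Xt) + (1 - alpha) * X
        residual = float(np.max(np.abs(Xn - Xt)))
        Xt = Xn
        if residual < tol:
            if return_info:
                return Xt, it, residual
            return Xt
    raise ConvergenceError(
        f"diffusion did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.3e})",
        residual=residual,
    )


def diffuse_closed_form(W, X0, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Solve (I - alpha W) Xss = (1 - alpha) X0 exactly.

    The system is nonsingular for alpha < 1 because the spectral radius
    of the symmetrically normalized adjacency is at most 1. Small
    systems use a dense LU solve; larger ones a sparse direct solve.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    Wm = _as_W(W)
    X = _as_X0(X0)
    n = Wm.shape[0]
    A = sp.identity(n, format="csc") - alpha * Wm.tocsc()
    if n <= 500:
        return np.linalg.solve(A.toarray(), (1 - alpha) * X)
    out = spla.spsolve(A, (1 - alpha) * X)
    return out[:, None] if out.ndim == 1 else out


def normalize_columns(Xss: np.ndarray) -> np.ndarray:
    """Divide each column by its maximum; all-zero columns stay zero."""
    Xss = np.asarray(Xss, dtype=float)
    maxes = Xss.max(axis=0)
    safe = np.where(maxes > 0, maxes, 1.0)
    return Xss / safe


def _padded_neighbor_index(net: Interactome) -> tuple[np.ndarray, np.ndarray]:
    """CSR neighbor lists padded to a rectangular (n, max_deg) array.

    Neighbor columns are ordered by ascending gene identifier within
    each row (CSR column order on a sorted node set), which fixes the
    tie order for top-m selection: equal scores break toward the
    lexicographically smaller gene.
    """
    A = net.adjacency
    n = A.shape[0]
    deg = np.diff(A.indptr)
    width = int(deg.max()) if n else 0
    idx = np.full((n, max(width, 1)), -1, dtype=np.int64)
    for i in range(n):
        nb = A.indices[A.indptr[i] : A.indptr[i + 1]]
        idx[i, : len(nb)] = nb
    return idx, deg


def top_neighbor_means(
    net: Interactome,
    Xstar: np.ndarray,
    m: int = 3,
    _padded: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Mean of each gene's top-m neighbor scores, per layer.

    A gene is not its own neighbor. Genes with fewer than m neighbors
    average over all of them; isolated genes score 0 in every layer.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    Xstar = np.asarray(Xstar, dtype=float)
    idx, deg = _padded if _padded is not None else _padded_neighbor_index(net)
    n, L = Xstar.shape
    Y = np.zeros((n, L))
    mask = idx >= 0  # (n, width)
    safe_idx = np.where(mask, idx, 0)
    denom = np.minimum(deg, m)
    denom_safe = np.where(denom > 0, denom, 1)
    for j in range(L):
        vals = np.where(mask, Xstar[safe_idx, j], -np.inf)
        k = min(m, vals.shape[1])
        top = -np.partition(-vals, k - 1, axis=1)[:, :k]
        top = np.where(np.isfinite(top), top, 0.0)
        Y[:, j] = top.sum(axis=1) / denom_safe
    Y[deg == 0] = 0.0
    return Y


def composite_score(Xstar: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """d_i = (sum over layers of x*_ij) * (sum over layers of y*_ij)."""
    Xstar = np.asarray(Xstar, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Xstar.shape != Y.shape:
        raise ValidationError(
            f"shape mismatch: Xstar {Xstar.shape} vs Y {Y.shape}"
        )
    return Xstar.sum(axis=1) * Y.sum(axis=1)


def _stat_from_Xss(net, Xss, statistic, m, padded) -> np.ndarray:
    if statistic == "xss":
        return Xss.sum(axis=1)
    Xstar = normalize_columns(Xss)
    Y = top_neighbor_means(net, Xstar, m=m, _padded=padded)
    return composite_score(Xstar, Y)


def permutation_pvalues(
    W,
    net: Interactome,
    X0,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 1000,
    seed: int | None = None,
    statistic: str = "d",
    m: int = 3,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Empirical per-gene p-values from row permutations of X0.

    Each permutation shuffles whole gene rows (keeping a gene's
    multi-layer profile intact), recomputes the full diffusion scoring,
    and contributes to p_i = (1 + #{perm: stat >= observed}) /
    (1 + n_perm); p = 0 is therefore unattainable. Permutation streams
    are derived from ``seed`` by permutation index, so results do not
    depend on evaluation order.
    """
    if seed is None:
        raise ValidationError("a seed is required for reproducible permutations")
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    if statistic not in ("d", "xss"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    Wm = _as_W(W)
    X = _as_X0(X0)
    n = Wm.shape[0]
    padded = _padded_neighbor_index(net) if statistic == "d" else None

    dense = n <= _DENSE_RESOLVENT_LIMIT
    if dense:
        resolvent = (1 - alpha) * np.linalg.inv(
            np.eye(n) - alpha * Wm.toarray()
        )
        solve = lambda seeds: resolvent @ seeds
    else:
        solve = lambda seeds: diffuse(Wm, seeds, alpha, tol, max_iter)

    observed = _stat_from_Xss(net, solve(X), statistic, m, padded)
    exceed = np.zeros(n, dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(n_perm)
    for ss in children:
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        stat = _stat_from_Xss(net, solve(X[perm]), statistic, m, padded)
        exceed += stat >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def select_core_extension(
    result: DiffusionResult,
    core: Sequence[str],
    p_max: float = 0.05,
    rule: str = "min_core",
) -> set[str]:
    """Non-core genes whose scores are comparable to the core's.

    Selected genes must be significant (p < ``p_max``) and pass the
    comparability rule: ``min_core`` requires score >= the minimum
    core-gene score; ``quantile:q`` requires score >= the q-quantile of
    core scores. Core genes never appear in the output.
    """
    core = set(core)
    if not core:
        raise ValidationError("core gene set is empty")
    if result.p is None:
        raise ValidationError("result carries no p-values; run permutations")
    stat = result.scores(result.statistic or "d")
    idx = {g: i for i, g in enumerate(result.genes)}
    core_scores = np.array([stat[idx[g]] for g in core if g in idx])
    if core_scores.size == 0:
        raise ValidationError("no core gene is present in the scored network")
    if rule == "min_core":
        cutoff = core_scores.min()
    elif rule.startswith("quantile:"):
        q = float(rule.split(":", 1)[1])
        cutoff = float(np.quantile(core_scores, q))
    else:
        raise ValidationError(f"unknown comparability rule {rule!r}")
    return {
        g
        for i, g in enumerate(result.genes)
        if g not in core and result.p[i] < p_max and stat[i] >= cutoff
    }


def score_genes(
    net: Interactome,
    W,
    X0,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    m: int = 3,
    n_perm: int = 0,
    seed: int | None = None,
    statistic: str = "d",
    method: str = "iterative",
) -> DiffusionResult:
    """Run the full scoring stage: diffusion, normalization, composite.

    With ``n_perm > 0`` empirical p-values for ``statistic`` are added.
    ``method`` selects the iterative fixed point (default) or the
    closed-form resolvent solve.
    """
    X = _as_X0(X0)
    layer_names = (
        X0.layer_names
        if isinstance(X0, EvidenceMatrix)
        else tuple(f"layer{j}" for j in range(X.shape[1]))
    )
    if method == "closed_form":
        Xss, iters, res = diffuse_closed_form(W, X, alpha), 0, 0.0
    else:
        Xss, iters, res = diffuse(W, X, alpha, tol, max_iter, return_info=True)
    Xstar = normalize_columns(Xss)
    Y = top_neighbor_means(net, Xstar, m=m)
    d = composite_score(Xstar, Y)
    result = DiffusionResult(
        genes=net.nodes,
        layer_names=layer_names,
        Xss=Xss,
        Xstar=Xstar,
        Y=Y,
        d=d,
        alpha=alpha,
        iterations=iters,
        residual=res,
    )
    if n_perm:
        result.p = permutation_pvalues(
            W, net, X, alpha, n_perm=n_perm, seed=seed,
            statistic=statistic, m=m, tol=tol, max_iter=max_iter,
        )
        result.statistic = statistic
    return result
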