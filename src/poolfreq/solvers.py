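"""Group-sparse ADMM solvers for maximum-parsimony pooled haplotype inference.

The estimation problem: given pooled allele-frequency observations
``A`` (L x O) and a haplotype dictionary ``H`` (L x M), find per-pool
haplotype proportion vectors — the columns of ``X`` (M x O) — that lie on the
probability simplex, satisfy the pool data, and use as few *distinct*
haplotypes as possible across all pools jointly.  Parsimony is relaxed to the
convex row-sparsity surrogate

    minimize  sum_j || X[j, :] ||_2
    subject to  H X = A,   1^T X = 1^T,   X >= 0,

a group lasso over rows with per-column simplex constraints, solved by the
alternating direction method of multipliers (ADMM) with the splitting X = Z:
the x-update is an equality-constrained least squares solved in closed form
through the Woodbury projector ``U4 = I - H^T (I + H H^T)^{-1} H``
(only the L x L system is ever factorized), and the z-update is the exact
proximal map of the row-norm objective plus nonnegativity: clipping to the
nonnegative orthant followed by row-wise group soft-thresholding
(``shrink``).  Dual variables are kept in scaled form (u = y / rho).

Three entry points share the engine:

- :func:`solve` — exact data constraint ``H X = A``;
- :func:`solve_noisy` — Frobenius-ball relaxation
  ``sum_i ||a_i - H x_i||^2 <= delta`` via a second split ``Z2 = H X`` and a
  Euclidean ball projection;
- :func:`solve_missing` — per-pool reduced constraints ``H_i x_i = a~_i``
  where each pool's masked loci are deleted from its own copy of ``H``; the
  row-wise shrink stays global, which is what couples the pools' supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .dictionary import HaplotypeDictionary
from .pools import PoolSet

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "Diagnostics",
    "shrink",
    "make_projector",
    "project_ball",
    "solve",
    "solve_noisy",
    "solve_missing",
    "row_norm_objective",
]


@dataclass
class SolverConfig:
    """Knobs of the ADMM iteration.

    Parameters
    ----------
    rho : float or None
        Augmented-Lagrangian penalty.  ``None`` (default) means the data-driven
        choice ``rho = 1 / a_bar`` with ``a_bar`` the mean observed allele-1
        relative frequency over all non-missing cells.
    tol : float
        Stop when ``||X_k - X_{k-1}|| / ||X_{k-1}|| < tol``.  The default
        ``1e-20`` is below double precision, so runs are iteration-capped.
    max_iter : int
        Iteration cap (default 8000).
    delta : float
        Squared Frobenius radius of the noise ball for :func:`solve_noisy`
        (default 0.1).
    seed : int or None
        Seed for any randomized component; the solvers themselves are
        deterministic, the field is carried for provenance.
    """

    rho: float | None = None
    tol: float = 1e-20
    max_iter: int = 8000
    delta: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rho is not None and not self.rho > 0:
            raise ValueError("rho must be positive")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")

    def resolve_rho(self, pool_set: PoolSet) -> float:
        if self.rho is not None:
            return self.rho
        a_bar = pool_set.mean_observed_frequency()
        if a_bar <= 0:
            return 1.0  # degenerate all-zero observations; any rho > 0 works
        return 1.0 / a_bar


@dataclass
class Diagnostics:
    """Convergence record returned alongside the proportion matrix."""

    n_iter: int
    rel_change: float
    data_residual: float
    split_residual: float
    objective: float
    rho: float
    converged: bool


def row_norm_objective(X: np.ndarray) -> float:
    """Row-sparsity surrogate: sum of row-wise Euclidean norms of ``X``."""
    return float(np.linalg.norm(np.atleast_2d(X), axis=1).sum())


def shrink(rows: np.ndarray, a: float) -> np.ndarray:
    """Row-wise group soft-thresholding.

    Each row ``r`` maps to ``max(||r||_2 - a, 0) * r / ||r||_2``; a zero row
    maps to the zero row with no division performed.
    """
    if not a > 0:
        raise ValueError("shrink threshold must be positive")
    R = np.atleast_2d(np.asarray(rows, dtype=float))
    norms = np.linalg.norm(R, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(norms[nz] - a, 0.0) / norms[nz]
    out = R * scale[:, np.newaxis]
    return out.reshape(np.shape(rows))


class RowSpaceProjector:
    """Implicit application of ``U4 = I - H^T (I + H H^T)^{-1} H``.

    ``U4`` is the inverse of ``I + H^T H`` by the Woodbury identity; only the
    L x L Gram system is factorized, so the M x M matrix (M can be ``2**L``)
    is never materialized.
    """

    def __init__(self, H: np.ndarray):
        H = np.asarray(H, dtype=float)
        L = H.shape[0]
        self.H = H
        self._chol = cho_factor(np.eye(L) + H @ H.T)
        ones = np.ones(H.shape[1])
        self.ones_image = self(ones)        # U4 @ 1
        self.ones_quad = float(ones @ self.ones_image)  # 1^T U4 1 > 0

    def __call__(self, V: np.ndarray) -> np.ndarray:
        """Apply ``U4`` to an M-vector or column-wise to an M x O matrix."""
        V = np.asarray(V, dtype=float)
        return V - self.H.T @ cho_solve(self._chol, self.H @ V)


def make_projector(dictionary: HaplotypeDictionary | np.ndarray) -> RowSpaceProjector:
    """Build the implicit ``U4`` operator for a dictionary (or raw matrix)."""
    H = dictionary.H if isinstance(dictionary, HaplotypeDictionary) else dictionary
    return RowSpaceProjector(H)


def project_ball(V: np.ndarray, A: np.ndarray, delta: float) -> np.ndarray:
    """Euclidean projection of ``V`` onto ``{Z : ||Z - A||_F^2 <= delta}``."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    V = np.asarray(V, dtype=float)
    A = np.asarray(A, dtype=float)
    if V.shape != A.shape:
        raise ValueError("shapes of V and A must match")
    dist_sq = float(((V - A) ** 2).sum())
    if dist_sq <= delta:
        return V.copy()
    return A + (V - A) * np.sqrt(delta / dist_sq)


def _check_inputs(pool_set: PoolSet, dictionary: HaplotypeDictionary) -> None:
    if dictionary.L != pool_set.L:
        raise ValueError(
            f"dictionary has {dictionary.L} loci but pool set has {pool_set.L}"
        )


def _constrained_x_update(proj: RowSpaceProjector, B: np.ndarray) -> np.ndarray:
    # per column: x = U4 (b - mu 1) with mu making 1^T x = 1
    U4B = proj(B)
    mu = (np.sum(U4B, axis=0) - 1.0) / proj.ones_quad
    return U4B - np.outer(proj.ones_image, mu)


def _z_update(X: np.ndarray, U1: np.ndarray, rho: float) -> np.ndarray:
    # exact proximal map of (1/rho) * (sum of row norms) + indicator(Z >= 0):
    # clip to the nonnegative orthant first, then group-shrink each row.
    # Shrinking before clipping is not a proximal map and admits rho-dependent
    # suboptimal fixed points (observed on dictionaries with near-collinear
    # columns); the order used here is the one the z-subproblem forces.
    return shrink(np.maximum(X + U1, 0.0), 1.0 / rho)


def _postprocess(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    out = np.maximum(Z, 0.0)
    sums = out.sum(axis=0)
    # a column of Z collapsing to zero is pathological; fall back to clipped X
    dead = sums <= 0
    if dead.any():
        out[:, dead] = np.maximum(X[:, dead], 0.0)
        sums = out.sum(axis=0)
        still = sums <= 0
        out[:, still] = 1.0 / out.shape[0]
        sums = out.sum(axis=0)
    out = out / sums
    # force column sums to exactly 1.0: push the ulp-level rounding residue
    # into each column's largest entry (a couple of passes suffice)
    for _ in range(3):
        residue = 1.0 - out.sum(axis=0)
        if not residue.any():
            break
        out[np.argmax(out, axis=0), np.arange(out.shape[1])] += residue
    return out


def _rel_change(X_new: np.ndarray, X_old: np.ndarray) -> float:
    denom = np.linalg.norm(X_old)
    if denom == 0.0:
        return np.inf
    return float(np.linalg.norm(X_new - X_old) / denom)


def solve(pool_set: PoolSet, dictionary: HaplotypeDictionary,
          config: SolverConfig | None = None) -> tuple[np.ndarray, Diagnostics]:
    """Noiseless joint row-sparse estimation with exact constraint ``H X = A``.

    Returns the M x O proportion matrix (columns exactly on the simplex after
    the final clip-and-renormalize) and a :class:`Diagnostics` record.
    """
    config = config or SolverConfig()
    _check_inputs(pool_set, dictionary)
    if pool_set.has_missing:
        raise ValueError("pool set has missing entries; use solve_missing")
    H, A = dictionary.H, pool_set.A
    M, O = dictionary.M, pool_set.O
    rho = config.resolve_rho(pool_set)
    proj = make_projector(dictionary)

    X = np.zeros((M, O))
    Z = np.zeros((M, O))
    U1 = np.zeros((M, O))
    U2 = np.zeros_like(A)
    rel = np.inf
    converged = False
    for k in range(1, config.max_iter + 1):
        B = H.T @ (A - U2) + (Z - U1)
        X_new = _constrained_x_update(proj, B)
        Z = _z_update(X_new, U1, rho)
        U1 = U1 + (X_new - Z)
        U2 = U2 + (H @ X_new - A)
        rel = _rel_change(X_new, X)
        X = X_new
        if not np.isfinite(rel) and k > 1:
            if not np.isfinite(X).all():
                raise FloatingPointError(f"non-finite iterate at iteration {k}")
        if rel < config.tol:
            converged = True
            break

    result = _postprocess(Z, X)
    diag = Diagnostics(
        n_iter=k, rel_change=rel,
        data_residual=float(np.linalg.norm(H @ X - A)),
        split_residual=float(np.linalg.norm(X - Z)),
        objective=row_norm_objective(result), rho=rho, converged=converged,
    )
    logger.debug("solve: %s", diag)
    return result, diag


def solve_noisy(pool_set: PoolSet, dictionary: HaplotypeDictionary,
                config: SolverConfig | None = None) -> tuple[np.ndarray, Diagnostics]:
    """Noise-tolerant estimation: ``sum_i ||a_i - H x_i||^2 <= delta``.

    The equality split ``Z2 = H X`` turns the ball constraint into a Euclidean
    projection (:func:`project_ball`); everything else mirrors :func:`solve`.
    """
    config = config or SolverConfig()
    _check_inputs(pool_set, dictionary)
    if pool_set.has_missing:
        raise ValueError("pool set has missing entries; use solve_missing")
    H, A = dictionary.H, pool_set.A
    M, O = dictionary.M, pool_set.O
    rho = config.resolve_rho(pool_set)
    delta = config.delta
    proj = make_projector(dictionary)

    X = np.zeros((M, O))
    Z1 = np.zeros((M, O))
    Z2 = np.zeros_like(A)
    U1 = np.zeros((M, O))
    U2 = np.zeros_like(A)
    rel = np.inf
    converged = False
    for k in range(1, config.max_iter + 1):
        B = H.T @ (Z2 - U2) + (Z1 - U1)
        X_new = _constrained_x_update(proj, B)
        Z1 = _z_update(X_new, U1, rho)
        Z2 = project_ball(H @ X_new + U2, A, delta)
        U1 = U1 + (X_new - Z1)
        U2 = U2 + (H @ X_new - Z2)
        rel = _rel_change(X_new, X)
        X = X_new
        if not np.isfinite(rel) and k > 1:
            if not np.isfinite(X).all():
                raise FloatingPointError(f"non-finite iterate at iteration {k}")
        if rel < config.tol:
            converged = True
            break

    result = _postprocess(Z1, X)
    diag = Diagnostics(
        n_iter=k, rel_change=rel,
        data_residual=float(np.linalg.norm(H @ X - A)),
        split_residual=float(np.linalg.norm(X - Z1)),
        objective=row_norm_objective(result), rho=rho, converged=converged,
    )
    logger.debug("solve_noisy: %s", diag)
    return result, diag


def _mask_groups(pool_set: PoolSet) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (observed-locus boolean vector, pool-index array) per distinct mask."""
    mask = pool_set.missing_mask
    keys: dict[bytes, list[int]] = {}
    for i in range(pool_set.O):
        keys.setdefault(mask[:, i].tobytes(), []).append(i)
    for key, idx in keys.items():
        col = np.frombuffer(key, dtype=bool)
        yield ~col, np.asarray(idx)


def solve_missing(pool_set: PoolSet, dictionary: HaplotypeDictionary,
                  config: SolverConfig | None = None) -> tuple[np.ndarray, Diagnostics]:
    """Estimation with per-pool missing loci: constraints ``H_i x_i = a~_i``.

    Each pool's x-update uses its own reduced dictionary ``H_i`` (masked rows
    deleted) with a per-mask Woodbury projector; projectors and Cholesky
    factors are cached per distinct mask, and pools sharing a mask are updated
    as one batch.  The row-wise shrink step stays shared across all pools,
    preserving the joint-sparsity coupling.  With an all-false mask the
    iteration reproduces :func:`solve` exactly.
    """
    config = config or SolverConfig()
    _check_inputs(pool_set, dictionary)
    H, A = dictionary.H, pool_set.A
    M, O = dictionary.M, pool_set.O
    rho = config.resolve_rho(pool_set)

    groups = []
    for keep, idx in _mask_groups(pool_set):
        if not keep.any():
            raise ValueError(
                f"pool {idx[0] + 1} has all loci missing and carries no information"
            )
        # reuse H itself for an all-observed group: a sliced copy can differ
        # in memory layout and perturb BLAS rounding, breaking the exact
        # agreement with solve() on mask-free pools
        Hi = H if keep.all() else H[keep, :]
        groups.append((keep, idx, Hi, make_projector(Hi)))

    X = np.zeros((M, O))
    Z = np.zeros((M, O))
    U1 = np.zeros((M, O))
    # per-pool dual blocks u2_i live in the observed rows of a full L x O array
    U2 = np.zeros_like(A)
    rel = np.inf
    converged = False
    for k in range(1, config.max_iter + 1):
        X_new = np.empty_like(X)
        for keep, idx, Hi, proj in groups:
            Ai = A[np.ix_(keep, idx)]
            U2i = U2[np.ix_(keep, idx)]
            B = Hi.T @ (Ai - U2i) + (Z[:, idx] - U1[:, idx])
            X_new[:, idx] = _constrained_x_update(proj, B)
        Z = _z_update(X_new, U1, rho)
        U1 = U1 + (X_new - Z)
        for keep, idx, Hi, proj in groups:
            U2[np.ix_(keep, idx)] += Hi @ X_new[:, idx] - A[np.ix_(keep, idx)]
        rel = _rel_change(X_new, X)
        X = X_new
        if not np.isfinite(rel) and k > 1:
            if not np.isfinite(X).all():
                raise FloatingPointError(f"non-finite iterate at iteration {k}")
        if rel < config.tol:
            converged = True
            break

    data_res_sq = 0.0
    for keep, idx, Hi, proj in groups:
        data_res_sq += float(
            ((Hi @ X[:, idx] - A[np.ix_(keep, idx)]) ** 2).sum()
        )
    result = _postprocess(Z, X)
    diag = Diagnostics(
        n_iter=k, rel_change=rel,
        data_residual=float(np.sqrt(data_res_sq)),
        split_residual=float(np.linalg.norm(X - Z)),
        objective=row_norm_objective(result), rho=rho, converged=converged,
    )
    logger.debug("solve_missing: %s", diag)
    return result, diag
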