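"""Independent reference solvers used as oracles in the tests.

These deliberately avoid the package's ADMM code path: the convex problems
(exact-constraint, noise-ball, and per-pool reduced-constraint row-sparse
estimation) are solved with a generic smooth constrained optimizer
(scipy trust-constr) on the smoothed objective
``sum_j sqrt(||X[j,:]||^2 + eps^2)``, and tiny recovery instances are checked
by exhaustive enumeration over 1- and 2-sparse simplex combinations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import LinearConstraint, NonlinearConstraint, minimize

EPS = 1e-9


def _objective(M: int, O: int):
    def fun(x):
        X = x.reshape(M, O)
        norms = np.sqrt((X ** 2).sum(axis=1) + EPS ** 2)
        return norms.sum()

    def jac(x):
        X = x.reshape(M, O)
        norms = np.sqrt((X ** 2).sum(axis=1) + EPS ** 2)
        return (X / norms[:, None]).ravel()

    return fun, jac


def _simplex_constraint(M: int, O: int) -> LinearConstraint:
    # 1^T X = 1^T on vec_C(X) (index j*O + i)
    S = np.kron(np.ones((1, M)), np.eye(O))
    return LinearConstraint(S, np.ones(O), np.ones(O))


def _solve(M, O, constraints, x0=None, maxiter=3000):
    fun, jac = _objective(M, O)
    if x0 is None:
        x0 = np.full(M * O, 1.0 / M)
    res = minimize(
        fun, x0, jac=jac, method="trust-constr",
        constraints=constraints,
        bounds=[(0.0, None)] * (M * O),
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": maxiter, "verbose": 0},
    )
    X = res.x.reshape(M, O)
    objective = float(np.linalg.norm(X, axis=1).sum())
    return X, objective


def oracle_exact(H: np.ndarray, A: np.ndarray, maxiter: int = 3000):
    """Row-sparse simplex estimation with the exact constraint H X = A."""
    L, M = H.shape
    O = A.shape[1]
    C = np.kron(H, np.eye(O))
    cons = [
        LinearConstraint(C, A.ravel(), A.ravel()),
        _simplex_constraint(M, O),
    ]
    return _solve(M, O, cons, maxiter=maxiter)


def oracle_noisy(H: np.ndarray, A: np.ndarray, delta: float, maxiter: int = 3000):
    """Row-sparse simplex estimation with sum_i ||a_i - H x_i||^2 <= delta."""
    L, M = H.shape
    O = A.shape[1]

    def g(x):
        X = x.reshape(M, O)
        R = H @ X - A
        return float((R ** 2).sum())

    def g_jac(x):
        X = x.reshape(M, O)
        R = H @ X - A
        return (2.0 * H.T @ R).ravel()

    cons = [
        NonlinearConstraint(g, -np.inf, delta, jac=g_jac),
        _simplex_constraint(M, O),
    ]
    return _solve(M, O, cons, maxiter=maxiter)


def oracle_missing(H: np.ndarray, A: np.ndarray, missing_mask: np.ndarray,
                   maxiter: int = 3000):
    """Row-sparse simplex estimation with per-pool reduced constraints."""
    L, M = H.shape
    O = A.shape[1]
    rows = []
    rhs = []
    for i in range(O):
        keep = ~missing_mask[:, i]
        Hi = H[keep, :]
        for r in range(Hi.shape[0]):
            row = np.zeros(M * O)
            row[np.arange(M) * O + i] = Hi[r, :]
            rows.append(row)
        rhs.extend(A[keep, i])
    C = np.array(rows)
    rhs = np.array(rhs)
    cons = [
        LinearConstraint(C, rhs, rhs),
        _simplex_constraint(M, O),
    ]
    return _solve(M, O, cons, maxiter=maxiter)


def best_sparse_fit(H: np.ndarray, a: np.ndarray):
    """Exhaustive best 1- or 2-sparse simplex representation of one pool.

    Returns (residual, weight vector) of the best fit over all single columns
    and all convex combinations of two columns (closed-form optimal weight).
    """
    L, M = H.shape
    best = (np.inf, None)
    for j in range(M):
        r = float(np.linalg.norm(H[:, j] - a))
        if r < best[0]:
            w = np.zeros(M)
            w[j] = 1.0
            best = (r, w)
    for j, k in combinations(range(M), 2):
        d = H[:, j] - H[:, k]
        denom = float(d @ d)
        if denom == 0:
            continue
        t = float(np.clip((a - H[:, k]) @ d / denom, 0.0, 1.0))
        fit = t * H[:, j] + (1 - t) * H[:, k]
        r = float(np.linalg.norm(fit - a))
        if r < best[0]:
            w = np.zeros(M)
            w[j], w[k] = t, 1 - t
            best = (r, w)
    return best
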