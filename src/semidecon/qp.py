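"""Quadratic-programming primitives for the coordinate-descent solver.

Two problem classes appear in the block updates:

* non-negative least squares  min_{x>=0} ||A x - d||^2, one small system
  per gene row, all rows sharing the same design matrix ``A``;
* the simplex-constrained QP  min_f 1/2 f'Hf - g'f  s.t. f >= 0,
  sum(f) = 1, one per bulk sample, with H = C'C positive semidefinite.

The row problems are solved with the exact Lawson-Hanson active-set
method (scipy.optimize.nnls), short-circuited by a vectorized
unconstrained solve whenever its minimizer is already feasible.  The
simplex QP is solved by a primal active-set method on the bound
constraints with the equality constraint kept in the KKT system.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

__all__ = ["nonneg_lstsq_rows", "solve_simplex_qp", "simplex_lsq"]


def nonneg_lstsq_rows(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Solve min_{x>=0} ||A x - d||^2 for every column d of D.

    Parameters
    ----------
    A : (q, k) shared design matrix.
    D : (q, r) right-hand sides, one problem per column.

    Returns
    -------
    X : (k, r) non-negative solutions.

    The unconstrained least-squares solution is computed for all
    columns at once; columns whose minimizer is already non-negative
    are accepted (a feasible unconstrained minimizer is a constrained
    minimizer), the rest fall back to exact NNLS.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    X, *_ = np.linalg.lstsq(A, D, rcond=None)
    scale = np.maximum(np.abs(X).max(axis=0, initial=1.0), 1.0)
    needs_nnls = np.flatnonzero((X < -1e-12 * scale).any(axis=0))
    for j in needs_nnls:
        X[:, j] = nnls(A, D[:, j])[0]
    np.clip(X, 0.0, None, out=X)
    return X


def _kkt_solve(H: np.ndarray, g: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimize 1/2 x'Hx - g'x s.t. sum(x)=1 and x[i]=0 off ``free``.

    Returns the stationary point restricted to the free coordinates and
    the equality-constraint multiplier nu (H_ff x_f - g_f = nu * 1).
    """
    nf = free.size
    M = np.zeros((nf + 1, nf + 1))
    M[:nf, :nf] = H[np.ix_(free, free)]
    M[:nf, nf] = -1.0
    M[nf, :nf] = 1.0
    rhs = np.append(g[free], 1.0)
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return sol[:nf], float(sol[nf])


def solve_simplex_qp(
    H: np.ndarray,
    g: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int | None = None,
) -> np.ndarray:
    """Minimize 1/2 f'Hf - g'f over the probability simplex.

    H must be symmetric positive semidefinite.  Uses a primal
    active-set method: starting from the uniform vector, repeatedly
    solve the equality-constrained KKT system on the currently free
    coordinates, step to the first blocking bound, and release the
    bound with the most negative multiplier at optimality checks.
    Ties among equally optimal solutions are broken by the
    deterministic pivoting order (documented: the minimizer is not
    unique when H is singular on the simplex).
    """
    H = np.asarray(H, dtype=float)
    g = np.asarray(g, dtype=float)
    K = g.size
    if K == 1:
        return np.ones(1)
    # scale-normalize so tolerances are meaningful at CPM magnitudes
    s = max(np.abs(H).max(), np.abs(g).max(), 1.0)
    H = H / s
    g = g / s
    x = np.full(K, 1.0 / K)
    active = np.zeros(K, dtype=bool)
    if max_iter is None:
        max_iter = 100 * K + 50
    for _ in range(max_iter):
        free = np.flatnonzero(~active)
        z, nu = _kkt_solve(H, g, free)
        xt = np.zeros(K)
        xt[free] = z
        p = xt - x
        if np.abs(p).max() <= tol:
            grad = H @ x - g
            if not active.any():
                break
            lam = grad[active] - nu
            if lam.min() >= -1e-9:
                break
            worst = np.flatnonzero(active)[int(np.argmin(lam))]
            active[worst] = False
            continue
        # longest feasible step toward the subproblem minimizer
        alpha = 1.0
        blocking = -1
        for i in free:
            if p[i] < -1e-15 and x[i] + p[i] < 0.0:
                a_i = x[i] / (-p[i])
                if a_i < alpha:
                    alpha = a_i
                    blocking = i
        x = x + alpha * p
        if blocking >= 0:
            x[blocking] = 0.0
            active[blocking] = True
    np.clip(x, 0.0, None, out=x)
    x /= x.sum()
    return x


def simplex_lsq(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin_f ||b - C f||^2 s.t. f >= 0, sum(f) = 1."""
    C = np.asarray(C, dtype=float)
    b = np.asarray(b, dtype=float)
    return solve_simplex_qp(C.T @ C, C.T @ b)
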