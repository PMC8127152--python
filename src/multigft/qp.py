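"""Deterministic solver for block-simplex-constrained convex QPs.

Problems of the form

    minimize    1/2 w^T H w + q^T w
    subject to  w >= 0,  sum(w_k) = s  for each of the d blocks w_k,

with ``H`` symmetric positive definite, arise from the edge-weight
reparameterization of graph Laplacian learning: each block is one paradigm's
upper-triangle weight vector and ``s = n/2`` encodes the trace constraint
``tr(L) = n``.

The solver runs an accelerated projected-gradient phase (FISTA with function
restarts; the feasible set projection is a per-block scaled-simplex
projection) to locate the neighbourhood of the unique minimizer, then a
primal-dual active-set polish that solves the reduced KKT system exactly.
When the polish verifies the KKT conditions the solution is accurate to
linear-solver precision; otherwise the projected-gradient iterate is returned
with a lowered status.  No randomness is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


@dataclass(frozen=True)
class BlockSimplexQP:
    H: np.ndarray
    q: np.ndarray
    n_blocks: int
    block_size: int
    block_sum: float

    def __post_init__(self) -> None:
        dm = self.n_blocks * self.block_size
        if self.H.shape != (dm, dm) or self.q.shape != (dm,):
            raise ValueError("inconsistent QP dimensions")
        if self.block_sum <= 0:
            raise ValueError("block_sum must be positive")

    def objective(self, x: np.ndarray) -> float:
        return float(0.5 * x @ self.H @ x + self.q @ x)


@dataclass(frozen=True)
class QPSolution:
    x: np.ndarray
    status: str  # "optimal" | "optimal_inaccurate" | "failed"
    n_iterations: int
    message: str = ""


def project_simplex_rows(V: np.ndarray, s: float) -> np.ndarray:
    """Euclidean projection of each row of ``V`` onto {w >= 0, sum w = s}."""
    n = V.shape[1]
    U = -np.sort(-V, axis=1)  # descending
    css = np.cumsum(U, axis=1) - s
    ind = np.arange(1, n + 1)
    cond = U - css / ind > 0
    rho = n - np.argmax(cond[:, ::-1], axis=1) - 1  # last True per row
    theta = css[np.arange(V.shape[0]), rho] / (rho + 1)
    return np.clip(V - theta[:, None], 0.0, None)


def _project(x: np.ndarray, qp: BlockSimplexQP) -> np.ndarray:
    V = x.reshape(qp.n_blocks, qp.block_size)
    return project_simplex_rows(V, qp.block_sum).ravel()


def _lipschitz(H: np.ndarray) -> float:
    """Upper bound on the largest eigenvalue via seeded power iteration."""
    v = np.ones(H.shape[0])
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(60):
        w = H @ v
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return 1.0
        lam = nw
        v = w / nw
    return 1.05 * lam


def _fista(
    qp: BlockSimplexQP, x0: np.ndarray, step: float, tol: float, max_iter: int
) -> tuple[np.ndarray, int, bool]:
    """Accelerated projected gradient with function-value restarts.

    Returns (iterate, iterations used, converged?) where convergence means
    the infinity norm of the projected-gradient step fell below ``tol``.
    """
    x = _project(x0, qp)
    y = x.copy()
    t = 1.0
    f_prev = qp.objective(x)
    for it in range(1, max_iter + 1):
        grad = qp.H @ y + qp.q
        x_new = _project(y - step * grad, qp)
        f_new = qp.objective(x_new)
        if f_new > f_prev:  # restart momentum
            y = x.copy()
            t = 1.0
            grad = qp.H @ y + qp.q
            x_new = _project(y - step * grad, qp)
            f_new = qp.objective(x_new)
        if np.max(np.abs(x_new - x)) < tol:
            return x_new, it, True
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t, f_prev = x_new, t_new, f_new
    return x, max_iter, False


def _active_set_polish(
    qp: BlockSimplexQP, x: np.ndarray, act_tol: float, max_iter: int = 60
) -> np.ndarray | None:
    """Primal-dual active-set refinement; returns the exact KKT point or
    ``None`` if the iteration fails to verify within ``max_iter`` steps."""
    d, m = qp.n_blocks, qp.block_size
    dm = d * m
    block_of = np.repeat(np.arange(d), m)
    active = x <= act_tol
    seen: set[bytes] = set()
    for _ in range(max_iter):
        free = ~active
        if any(not np.any(free[k * m : (k + 1) * m]) for k in range(d)):
            return None  # a block cannot have an empty support
        key = np.packbits(active).tobytes()
        if key in seen:
            return None  # cycling
        seen.add(key)
        idx_f = np.flatnonzero(free)
        nf = idx_f.size
        E = np.zeros((d, nf))
        E[block_of[idx_f], np.arange(nf)] = 1.0
        K = np.zeros((nf + d, nf + d))
        K[:nf, :nf] = qp.H[np.ix_(idx_f, idx_f)]
        K[:nf, nf:] = E.T
        K[nf:, :nf] = E
        rhs = np.concatenate([-qp.q[idx_f], np.full(d, qp.block_sum)])
        try:
            sol = scipy.linalg.solve(K, rhs, assume_a="sym")
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
            return None
        if not np.all(np.isfinite(sol)):
            return None
        x_full = np.zeros(dm)
        x_full[idx_f] = sol[:nf]
        nu = sol[nf:]
        lam = qp.H @ x_full + qp.q + nu[block_of]
        lam[idx_f] = 0.0
        prim_ok = x_full.min() >= -1e-11 * max(1.0, qp.block_sum)
        dual_ok = lam.min() >= -1e-9 * max(1.0, float(np.abs(qp.q).max()))
        if prim_ok and dual_ok:
            x_opt = np.clip(x_full, 0.0, None)
            # restore exact block sums perturbed by the clip
            V = x_opt.reshape(d, m)
            sums = V.sum(axis=1)
            V *= (qp.block_sum / sums)[:, None]
            return V.ravel()
        active = (x_full - lam) < 0.0
    return None


def solve_block_simplex_qp(
    qp: BlockSimplexQP, tol: float = 1e-9, max_iterations: int = 100_000
) -> QPSolution:
    dm = qp.n_blocks * qp.block_size
    scale = qp.block_sum / qp.block_size
    x0 = np.full(dm, scale)  # uniform graph: always feasible
    step = 1.0 / _lipschitz(qp.H)

    # coarse localisation, then exact polish
    coarse_tol = max(1e-4 * scale, tol)
    x, it1, _ = _fista(qp, x0, step, coarse_tol, min(2000, max_iterations))
    for act_tol in (1e-8 * scale, 1e-6 * scale):
        polished = _active_set_polish(qp, x, act_tol)
        if polished is not None:
            return QPSolution(polished, "optimal", it1)

    # fall back to a fine projected-gradient solve
    x, it2, converged = _fista(qp, x, step, tol * scale, max_iterations)
    polished = _active_set_polish(qp, x, 1e-8 * scale)
    if polished is not None:
        return QPSolution(polished, "optimal", it1 + it2)
    if converged:
        return QPSolution(x, "optimal_inaccurate", it1 + it2, "active-set polish failed")
    return QPSolution(
        x, "failed", it1 + it2, "projected gradient did not converge"
    )
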