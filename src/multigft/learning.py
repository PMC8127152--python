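"""Joint multigraph Laplacian learning as a constrained convex QP.

Given signal matrices ``X^(k)`` (one per paradigm, k = 1..d, all on the same
``n`` nodes), one graph Laplacian per paradigm is estimated by minimizing

    (1/d) * sum_k [ tr(X_k^T L_k X_k) + beta * ||L_k||_F^2 ]
           + sum_{i,j} alpha_ij * ||L_i - L_j||_F^2

subject to ``tr(L_k) = n``, ``L_k`` symmetric with nonpositive off-diagonal,
and ``L_k 1 = 0``.  The trace term rewards Laplacians on which the observed
signals are smooth, the Frobenius term controls how spread-out the learned
weights are, and the coupling term pulls the per-paradigm networks toward a
shared structure (alpha = 0 decouples the paradigms; alpha -> infinity forces
identical networks).  The coupling sum runs over ordered pairs, so each
unordered paradigm pair is counted twice.

The problem is reparameterized in the stacked upper-triangle weight vectors
``w^(k) >= 0`` (with ``L_k`` reconstructed as ``diag(B w) - W``), which turns
the Laplacian validity constraints into simple bounds plus one equality
``sum(w^(k)) = n/2`` per paradigm.  The resulting QP is strictly convex and is
solved by an accelerated projected-gradient method with an active-set polish
(see :mod:`multigft.qp`).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .graphs import LaplacianMatrix, SignalSet, pairwise_squared_distances
from .qp import BlockSimplexQP, QPSolution, solve_block_simplex_qp

logger = logging.getLogger(__name__)


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    OPTIMAL_INACCURATE = "optimal_inaccurate"
    FAILED = "failed"


@dataclass(frozen=True)
class MultiParadigmSet:
    """Ordered collection of per-paradigm signal sets sharing the node set."""

    paradigms: tuple[SignalSet, ...]
    paradigm_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        paradigms = tuple(self.paradigms)
        object.__setattr__(self, "paradigms", paradigms)
        if not paradigms:
            raise ValueError("at least one paradigm required")
        n = paradigms[0].n_nodes
        for k, p in enumerate(paradigms):
            if p.n_nodes != n:
                raise ValueError(
                    f"paradigm {k} has {p.n_nodes} nodes, expected {n}"
                )
        names = tuple(self.paradigm_names) or tuple(
            f"paradigm_{k + 1}" for k in range(len(paradigms))
        )
        if len(names) != len(paradigms):
            raise ValueError("paradigm_names length mismatch")
        object.__setattr__(self, "paradigm_names", names)

    @property
    def d(self) -> int:
        return len(self.paradigms)

    @property
    def n_nodes(self) -> int:
        return self.paradigms[0].n_nodes


@dataclass(frozen=True)
class LearningConfig:
    """Hyper-parameters of the joint learning objective.

    ``alpha`` may be a scalar (broadcast to every off-diagonal paradigm pair,
    the default — only the alpha/beta ratio is tuned in practice) or a full
    ``d x d`` symmetric nonnegative matrix with zero diagonal.
    """

    beta: float
    alpha: float | np.ndarray = 0.0
    solver_tolerance: float = 1e-9
    max_iterations: int = 100_000

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta!r}")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")

    def alpha_matrix(self, d: int) -> np.ndarray:
        if np.isscalar(self.alpha):
            a = float(self.alpha)
            if a < 0:
                raise ValueError("alpha must be nonnegative")
            if d == 1 and a != 0.0:
                raise ValueError("nonzero alpha is meaningless with a single paradigm")
            mat = np.full((d, d), a)
            np.fill_diagonal(mat, 0.0)
            return mat
        mat = np.asarray(self.alpha, dtype=float)
        if mat.shape != (d, d):
            raise ValueError(f"alpha matrix must be {d}x{d}, got {mat.shape}")
        if np.any(mat < 0):
            raise ValueError("alpha entries must be nonnegative")
        if not np.allclose(mat, mat.T):
            raise ValueError("alpha matrix must be symmetric")
        if np.any(np.diag(mat) != 0):
            raise ValueError("alpha diagonal must be zero")
        return mat


@dataclass(frozen=True)
class LearningResult:
    laplacians: tuple[LaplacianMatrix, ...]
    objective_value: float
    solver_status: SolverStatus
    config_used: LearningConfig
    n_iterations: int = 0


def incidence_matrix(n: int) -> np.ndarray:
    """Unsigned node-edge incidence ``B`` (n x n(n-1)/2): B[i, e] = 1 iff
    node i is an endpoint of edge e, edges in upper-triangle order."""
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size
    B = np.zeros((n, m))
    cols = np.arange(m)
    B[iu, cols] = 1.0
    B[ju, cols] = 1.0
    return B


def frobenius_operator(n: int) -> np.ndarray:
    """Matrix ``M`` with ``||L(w)||_F^2 = w^T M w`` for the Laplacian built
    from edge weights ``w``: off-diagonals contribute ``2 w_e^2`` each, the
    diagonal (degrees ``B w``) contributes ``w^T B^T B w``."""
    B = incidence_matrix(n)
    m = B.shape[1]
    return 2.0 * np.eye(m) + B.T @ B


def laplacian_from_edge_vector(w: np.ndarray, n: int) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    W = np.zeros((n, n))
    W[iu, ju] = w
    W += W.T
    return np.diag(W.sum(axis=1)) - W


def smoothness_coefficients(X: SignalSet) -> np.ndarray:
    """Linear QP coefficients ``z_e = sum_t (x_i(t) - x_j(t))^2`` per edge.

    These implement ``tr(X^T L X) = sum_e w_e z_e`` for the reconstructed
    Laplacian (the half in the weighted-difference identity cancels the
    double count over ordered pairs).
    """
    d2 = pairwise_squared_distances(X)
    iu, ju = np.triu_indices(X.n_nodes, k=1)
    return d2[iu, ju]


def assemble_qp(data: MultiParadigmSet, config: LearningConfig) -> BlockSimplexQP:
    """Build the stacked-edge-weight QP ``min 1/2 w^T H w + q^T w`` over the
    product of per-paradigm scaled simplices ``{w_k >= 0, sum(w_k) = n/2}``."""
    n, d = data.n_nodes, data.d
    if n < 2:
        raise ValueError("need at least 2 nodes to learn a graph")
    alpha = config.alpha_matrix(d)
    M = frobenius_operator(n)
    m = M.shape[0]
    H = np.zeros((d * m, d * m))
    q = np.empty(d * m)
    for k in range(d):
        sl = slice(k * m, (k + 1) * m)
        q[sl] = smoothness_coefficients(data.paradigms[k]) / d
        H[sl, sl] = (2.0 * config.beta / d) * M
    # ordered-pair coupling: sum_{i != j} alpha_ij ||L_i - L_j||_F^2
    for i in range(d):
        for j in range(i + 1, d):
            if alpha[i, j] == 0.0:
                continue
            c = 4.0 * alpha[i, j]  # 2 (ordered pairs) x 2 (Hessian of square)
            si, sj = slice(i * m, (i + 1) * m), slice(j * m, (j + 1) * m)
            H[si, si] += c * M
            H[sj, sj] += c * M
            H[si, sj] -= c * M
            H[sj, si] -= c * M
    return BlockSimplexQP(H=H, q=q, n_blocks=d, block_size=m, block_sum=n / 2.0)


def objective_value(
    laplacians: list[LaplacianMatrix] | tuple[LaplacianMatrix, ...],
    data: MultiParadigmSet,
    config: LearningConfig,
) -> float:
    """Evaluate the joint objective directly from Laplacian matrices.

    Used as the independent check of solver output (never read back from the
    solver's internal objective).
    """
    d = data.d
    if len(laplacians) != d:
        raise ValueError(f"{len(laplacians)} Laplacians for {d} paradigms")
    alpha = config.alpha_matrix(d)
    total = 0.0
    mats = [L.matrix for L in laplacians]
    for k in range(d):
        X = data.paradigms[k].values
        total += (np.trace(X.T @ mats[k] @ X) + config.beta * np.sum(mats[k] ** 2)) / d
    for i in range(d):
        for j in range(d):
            if i != j and alpha[i, j] != 0.0:
                total += alpha[i, j] * np.sum((mats[i] - mats[j]) ** 2)
    return float(total)


def _result_from_solution(
    sol: QPSolution, data: MultiParadigmSet, config: LearningConfig
) -> LearningResult:
    n, d = data.n_nodes, data.d
    m = sol.x.size // d
    if sol.status == "failed":
        logger.error("QP solver failed: %s", sol.message)
        return LearningResult((), np.nan, SolverStatus.FAILED, config, sol.n_iterations)
    laps = []
    for k in range(d):
        w = np.clip(sol.x[k * m : (k + 1) * m], 0.0, None)
        laps.append(LaplacianMatrix(laplacian_from_edge_vector(w, n)))
    status = (
        SolverStatus.OPTIMAL if sol.status == "optimal" else SolverStatus.OPTIMAL_INACCURATE
    )
    obj = objective_value(laps, data, config)
    return LearningResult(tuple(laps), obj, status, config, sol.n_iterations)


def learn_multigraph(data: MultiParadigmSet, config: LearningConfig) -> LearningResult:
    """Jointly estimate one Laplacian per paradigm.

    The problem is strictly convex (beta > 0), so the minimizer is unique and
    the solve is deterministic.  The uniform graph (all weights equal) is
    always feasible; an infeasibility report is treated as solver failure.
    """
    qp = assemble_qp(data, config)
    sol = solve_block_simplex_qp(
        qp, tol=config.solver_tolerance, max_iterations=config.max_iterations
    )
    return _result_from_solution(sol, data, config)


def learn_single_laplacian(
    X: SignalSet,
    beta: float,
    solver_tolerance: float = 1e-9,
    max_iterations: int = 100_000,
) -> LearningResult:
    """Single-paradigm special case (d = 1, no coupling term)."""
    data = MultiParadigmSet((X,))
    config = LearningConfig(
        beta=beta,
        alpha=0.0,
        solver_tolerance=solver_tolerance,
        max_iterations=max_iterations,
    )
    return learn_multigraph(data, config)
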