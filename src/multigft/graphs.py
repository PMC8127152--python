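"""Graph, Laplacian and affinity primitives.

A functional connectivity network is represented by a symmetric, nonnegative
weighted adjacency matrix ``W`` over ``n`` nodes (brain regions), and its
combinatorial graph Laplacian ``L = D - W`` where ``D`` is the diagonal degree
matrix.  ``L`` is positive semidefinite, its rows sum to zero and the constant
vector spans (at least) its null space.  All containers here are dense; every
use case in this package involves at most a few hundred nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Relative tolerance for Laplacian validity checks.  QP solver outputs are
#: inexact, so validity is enforced only up to this scale-relative slack.
LAPLACIAN_RTOL = 1e-8


class GraphValidationError(ValueError):
    """Raised when a matrix violates a graph/Laplacian invariant."""


def _as_square_array(matrix, name: str) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise GraphValidationError(f"{name} must be a square matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GraphValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph with nonnegative edge weights and zero diagonal.

    Parameters
    ----------
    weights
        ``n x n`` symmetric matrix of nonnegative reals with zero diagonal.
    node_labels
        Optional list of ``n`` node names (e.g. atlas region labels).
    """

    weights: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = _as_square_array(self.weights, "weights")
        object.__setattr__(self, "weights", w)
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise GraphValidationError(f"negative weight at ({i}, {j}): {w[i, j]!r}")
        asym = np.argwhere(~np.isclose(w, w.T, rtol=1e-10, atol=1e-12))
        if asym.size:
            i, j = asym[0]
            raise GraphValidationError(
                f"asymmetric weights at ({i}, {j}): {w[i, j]!r} != {w[j, i]!r}"
            )
        if np.any(np.abs(np.diag(w)) > 0):
            i = int(np.argmax(np.abs(np.diag(w))))
            raise GraphValidationError(f"nonzero diagonal at node {i}: {w[i, i]!r}")
        if self.node_labels is not None and len(self.node_labels) != w.shape[0]:
            raise GraphValidationError(
                f"{len(self.node_labels)} labels for {w.shape[0]} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle weights as a length ``n(n-1)/2`` vector."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu, ju]


@dataclass(frozen=True)
class LaplacianMatrix:
    """Valid combinatorial graph Laplacian ``L = D - W``.

    Invariants (checked within :data:`LAPLACIAN_RTOL` relative tolerance):
    symmetric; off-diagonal entries nonpositive; rows sum to zero; diagonal
    nonnegative.
    """

    matrix: np.ndarray
    rtol: float = field(default=LAPLACIAN_RTOL, repr=False)

    def __post_init__(self) -> None:
        m = _as_square_array(self.matrix, "Laplacian")
        object.__setattr__(self, "matrix", m)
        scale = max(float(np.abs(m).max()), 1.0)
        tol = self.rtol * scale
        if np.abs(m - m.T).max() > tol:
            raise GraphValidationError("Laplacian is not symmetric")
        off = m - np.diag(np.diag(m))
        bad = np.argwhere(off > tol)
        if bad.size:
            i, j = bad[0]
            raise GraphValidationError(
                f"positive off-diagonal Laplacian entry at ({i}, {j}): {m[i, j]!r}"
            )
        rs = m.sum(axis=1)
        if np.abs(rs).max() > tol * m.shape[0]:
            i = int(np.argmax(np.abs(rs)))
            raise GraphValidationError(f"row {i} sums to {rs[i]!r}, expected 0")
        if np.any(np.diag(m) < -tol):
            i = int(np.argmax(-np.diag(m)))
            raise GraphValidationError(f"negative diagonal at node {i}: {m[i, i]!r}")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


@dataclass(frozen=True)
class SignalSet:
    """Graph signals: an ``n x p`` matrix, rows = nodes, columns = observations.

    Each column is one graph signal (e.g. all regions' activity at one time
    point); each row is one node's observation series.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise GraphValidationError(f"signal matrix must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise GraphValidationError("signal matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]


def upper_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, edge-vector order."""
    return np.triu_indices(n, k=1)


def laplacian_from_adjacency(graph: WeightedGraph) -> LaplacianMatrix:
    """``L = D - W`` with ``D = diag(row sums of W)``."""
    w = graph.weights
    return LaplacianMatrix(np.diag(w.sum(axis=1)) - w)


def adjacency_from_laplacian(
    L: LaplacianMatrix, node_labels: list[str] | None = None
) -> WeightedGraph:
    """Recover the weighted adjacency ``W_ij = -L_ij`` (i != j).

    Off-diagonal entries that are positive within the Laplacian's tolerance
    (solver round-off) are clipped to zero weight.
    """
    m = L.matrix
    w = -(m - np.diag(np.diag(m)))
    w = np.clip(0.5 * (w + w.T), 0.0, None)
    return WeightedGraph(w, node_labels=node_labels)


def pairwise_squared_distances(X: SignalSet) -> np.ndarray:
    """``n x n`` matrix of squared Euclidean distances between node rows."""
    v = X.values
    sq = np.sum(v * v, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
    np.fill_diagonal(d2, 0.0)
    return np.clip(d2, 0.0, None)


def median_pairwise_distance(X: SignalSet) -> float:
    """Median off-diagonal Euclidean distance between node rows.

    The documented default bandwidth for :func:`rbf_affinity`.
    """
    d2 = pairwise_squared_distances(X)
    iu, ju = np.triu_indices(X.n_nodes, k=1)
    med = float(np.median(np.sqrt(d2[iu, ju])))
    return med if med > 0 else 1.0


def rbf_affinity(
    X: SignalSet,
    sigma: float | None = None,
    edge_rule: str | tuple[str, int] = "complete",
) -> WeightedGraph:
    """Gaussian (RBF) kernel affinity graph over node observation rows.

    ``W_ij = exp(-||x^i - x^j||^2 / (2 sigma^2))`` for node pairs joined by
    ``edge_rule``, zero otherwise.

    Parameters
    ----------
    sigma
        Kernel bandwidth; must be positive.  ``None`` uses the median
        pairwise distance between node rows.
    edge_rule
        ``"complete"`` (default) connects every pair; ``("knn", k)`` keeps
        each node's ``k`` nearest neighbours and symmetrizes by union.
    """
    if sigma is None:
        sigma = median_pairwise_distance(X)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    d2 = pairwise_squared_distances(X)
    w = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    if edge_rule == "complete":
        return WeightedGraph(w)
    if isinstance(edge_rule, tuple) and len(edge_rule) == 2 and edge_rule[0] == "knn":
        k = int(edge_rule[1])
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        n = X.n_nodes
        if np.allclose(d2, 0.0):
            warnings.warn(
                "all node rows identical under kNN rule; ties broken by node index",
                stacklevel=2,
            )
        mask = np.zeros((n, n), dtype=bool)
        for i in range(n):
            d = d2[i].copy()
            d[i] = np.inf
            # stable sort -> ties broken toward the lowest node index
            nbrs = np.argsort(d, kind="stable")[:k]
            mask[i, nbrs] = True
        mask |= mask.T
        return WeightedGraph(np.where(mask, w, 0.0))
    raise ValueError(f"unknown edge_rule {edge_rule!r}")


def binarize_edges(L: LaplacianMatrix, threshold: float = 1e-4) -> np.ndarray:
    """Binary edge indicator over the strict upper triangle.

    Edge ``(i, j)`` is present iff ``|L_ij| > threshold`` — equivalently the
    learned weight exceeds the threshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    iu, ju = np.triu_indices(L.n_nodes, k=1)
    return np.abs(L.matrix[iu, ju]) > threshold


def edge_set_from_vector(edges: np.ndarray, n: int) -> set[tuple[int, int]]:
    """Convert an upper-triangle indicator vector to a set of (i, j) pairs."""
    iu, ju = np.triu_indices(n, k=1)
    return {(int(i), int(j)) for i, j, e in zip(iu, ju, edges) if e}
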