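"""Graph Fourier analysis: Laplacian eigendecomposition, the GFT pair,
smoothness, ideal frequency-band filters, and the adjacency-eigenbasis
alternative transform.

The Laplacian eigenvalues play the role of frequencies: an eigenvector
``f_k`` satisfies ``S(f_k) = f_k^T L f_k = lambda_k``, so small eigenvalues
correspond to signals that vary slowly over the graph.  Frequency indexing
throughout the package is by ascending-eigenvalue *rank* (a cutoff ``l``
selects the ``l`` smoothest eigenbases), matching how low-frequency cutoffs
are specified in connectivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import LaplacianMatrix, SignalSet, WeightedGraph


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenpairs of a Laplacian, ascending eigenvalue order.

    ``eigenvectors[:, i]`` pairs with ``eigenvalues[i]``; the matrix is
    orthonormal and each column's sign is fixed so its first entry whose
    magnitude exceeds a small tolerance is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.size


@dataclass(frozen=True)
class SpectrumCoefficients:
    """GFT coefficients: row i is eigenbasis i across the p observations."""

    coefficients: np.ndarray
    basis_ref: SpectralDecomposition = field(repr=False)


@dataclass(frozen=True)
class FilterBank:
    """Ideal (brick-wall) three-band split by eigenvalue rank.

    The low band keeps eigenbases ``1..l`` (1-based), the mid band
    ``l+1..high_cutoff``, the high band the rest.  ``high_cutoff`` defaults
    to ``max(l, n - l)``, making the low and high bands symmetric.
    """

    low_cutoff: int
    high_cutoff: int

    def __post_init__(self) -> None:
        if not 1 <= self.low_cutoff <= self.high_cutoff:
            raise ValueError(
                f"need 1 <= low_cutoff <= high_cutoff, got "
                f"({self.low_cutoff}, {self.high_cutoff})"
            )

    @classmethod
    def with_default_high(cls, low_cutoff: int, n: int) -> "FilterBank":
        return cls(low_cutoff, max(low_cutoff, n - low_cutoff))


def _fix_signs(F: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic sign convention: first non-negligible entry positive."""
    F = F.copy()
    for k in range(F.shape[1]):
        col = F[:, k]
        nz = np.flatnonzero(np.abs(col) > tol)
        pivot = nz[0] if nz.size else 0
        if col[pivot] < 0:
            F[:, k] = -col
    return F


def eigendecompose(L: LaplacianMatrix) -> SpectralDecomposition:
    """Full symmetric eigendecomposition ``L = F diag(lambda) F^T``."""
    lam, F = np.linalg.eigh(L.matrix)
    lam = np.clip(lam, 0.0, None)  # PSD up to round-off
    return SpectralDecomposition(lam, _fix_signs(F))


def gft(x: SignalSet, decomp: SpectralDecomposition) -> SpectrumCoefficients:
    """Forward transform ``x~ = F^T x`` (columns transformed independently)."""
    if x.n_nodes != decomp.n_nodes:
        raise ValueError(f"signal has {x.n_nodes} nodes, basis has {decomp.n_nodes}")
    return SpectrumCoefficients(decomp.eigenvectors.T @ x.values, decomp)


def igft(coeffs: SpectrumCoefficients, decomp: SpectralDecomposition | None = None) -> SignalSet:
    """Inverse transform ``x = F x~``; exact inverse of :func:`gft`."""
    d = decomp if decomp is not None else coeffs.basis_ref
    if coeffs.coefficients.shape[0] != d.n_nodes:
        raise ValueError("coefficient/basis dimension mismatch")
    return SignalSet(d.eigenvectors @ coeffs.coefficients)


def smoothness(x, L: LaplacianMatrix) -> float:
    """Laplacian quadratic form ``S(x) = x^T L x``.

    Equals the weighted-difference sum ``1/2 sum_ij W_ij (x(i) - x(j))^2``,
    hence nonnegative; constant signals score 0 and eigenvectors score their
    eigenvalue.
    """
    v = np.asarray(getattr(x, "values", x), dtype=float).ravel()
    if v.size != L.n_nodes:
        raise ValueError(f"signal length {v.size} != {L.n_nodes} nodes")
    return float(v @ L.matrix @ v)


def filter_components(
    x: SignalSet, decomp: SpectralDecomposition, bank: FilterBank
) -> tuple[SignalSet, SignalSet, SignalSet]:
    """Split a signal set into low/mid/high frequency components.

    The three reconstructed components sum to the input exactly (disjoint
    eigenspace projections) and are mutually orthogonal per column.
    """
    n = decomp.n_nodes
    if bank.high_cutoff > n:
        raise ValueError(f"high_cutoff {bank.high_cutoff} exceeds n={n}")
    coeffs = gft(x, decomp).coefficients
    out = []
    for lo, hi in ((0, bank.low_cutoff), (bank.low_cutoff, bank.high_cutoff), (bank.high_cutoff, n)):
        masked = np.zeros_like(coeffs)
        masked[lo:hi] = coeffs[lo:hi]
        out.append(SignalSet(decomp.eigenvectors @ masked))
    return tuple(out)


def agft_baseline(X: SignalSet, W: WeightedGraph) -> SpectrumCoefficients:
    """Transform with respect to the adjacency-matrix eigenbasis.

    Eigenvalues are sorted descending — for an adjacency matrix the largest
    eigenvalue corresponds to the smoothest mode, mirroring the ascending
    Laplacian convention.  Only symmetric (diagonalizable) adjacency
    matrices are supported.
    """
    if X.n_nodes != W.n_nodes:
        raise ValueError("signal/graph dimension mismatch")
    lam, V = np.linalg.eigh(W.weights)
    order = np.argsort(-lam, kind="stable")
    decomp = SpectralDecomposition(lam[order], _fix_signs(V[:, order]))
    return SpectrumCoefficients(decomp.eigenvectors.T @ X.values, decomp)
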