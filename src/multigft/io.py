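"""Delimited-text I/O for signal matrices, square matrices, edge lists and
node-label tables.

All user-facing tables use 1-based node indexing (atlas convention); arrays
in memory are 0-based.  Matrices are written with a header row of node
labels so files round-trip with their labels attached.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import LaplacianMatrix, SignalSet, WeightedGraph

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files, with row/column context."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_signal_matrix(path: str | Path, transpose: bool = False) -> SignalSet:
    """Read a nodes x observations matrix from CSV/TSV (no header row).

    ``transpose=True`` reads observation-major files (rows = time points).
    Raises :class:`ParseError` naming the offending line/column for ragged
    rows, non-numeric cells or empty files.
    """
    path = Path(path)
    sep = _sep_for(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = [c.strip() for c in line.rstrip("\n").split(sep)]
            parsed = []
            for col, cell in enumerate(cells, start=1):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                        f"column {col}"
                    ) from None
            if rows and len(parsed) != len(rows[0]):
                raise ParseError(
                    f"{path}: line {lineno} has {len(parsed)} cells, "
                    f"expected {len(rows[0])}"
                )
            rows.append(parsed)
    if not rows:
        raise ParseError(f"{path}: empty file")
    values = np.asarray(rows)
    if transpose:
        values = values.T
    sig = SignalSet(values)
    logger.info("read %s: %d nodes x %d observations", path, sig.n_nodes, sig.n_obs)
    return sig


def write_signal_matrix(path: str | Path, X: SignalSet) -> None:
    path = Path(path)
    np.savetxt(path, X.values, delimiter=_sep_for(path), fmt="%.17g")


def write_square_matrix(
    path: str | Path, matrix: np.ndarray, node_labels: list[str] | None = None
) -> None:
    """Write a square matrix with a header row of node labels."""
    path = Path(path)
    n = matrix.shape[0]
    labels = node_labels if node_labels is not None else [f"n{i + 1}" for i in range(n)]
    df = pd.DataFrame(matrix, columns=labels)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_square_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    matrix = df.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1]:
        raise ParseError(
            f"{path}: matrix is {matrix.shape[0]}x{matrix.shape[1]}, expected square"
        )
    return matrix, list(df.columns)


def read_laplacian(path: str | Path) -> LaplacianMatrix:
    matrix, _ = read_square_matrix(path)
    return LaplacianMatrix(matrix)


def read_weighted_graph(path: str | Path) -> WeightedGraph:
    matrix, labels = read_square_matrix(path)
    return WeightedGraph(matrix, node_labels=labels)


def write_edge_list(path: str | Path, graph: WeightedGraph) -> None:
    """Write (node_i, node_j, weight) rows, 1-based, upper triangle only."""
    iu, ju = np.triu_indices(graph.n_nodes, k=1)
    w = graph.weights[iu, ju]
    keep = w > 0
    df = pd.DataFrame(
        {"node_i": iu[keep] + 1, "node_j": ju[keep] + 1, "weight": w[keep]}
    )
    df.to_csv(Path(path), index=False)


def read_node_table(path: str | Path) -> pd.DataFrame:
    """Read a node-label table: columns ``index`` (1-based), ``label`` and
    optional MNI ``x``/``y``/``z`` coordinates."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"index", "label"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: node table needs columns {sorted(required)}")
    idx = df["index"].to_numpy()
    n = len(df)
    if not np.array_equal(np.sort(idx), np.arange(1, n + 1)):
        raise ParseError(f"{path}: node indices must be contiguous 1..{n}")
    if df["label"].duplicated().any():
        dup = df.loc[df["label"].duplicated(), "label"].iloc[0]
        raise ParseError(f"{path}: duplicate node label {dup!r}")
    return df.sort_values("index").reset_index(drop=True)
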