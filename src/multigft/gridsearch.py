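"""Cohort-level hyper-parameter grid search.

Bridges the pipeline's manifest data to :func:`multigft.evaluation.grid_search`:
for each (alpha, beta) the per-subject networks are learned once and cached;
the cutoff ``l`` enters through the per-node low-band energy profile appended
to the vectorized Laplacians, so every (alpha, beta, l) triple yields its own
feature matrix and CV accuracy.
"""

from __future__ import annotations

import numpy as np

from .evaluation import GridSearchResult, grid_search
from .hubs import projection_energy
from .io import read_signal_matrix
from .learning import LearningConfig, MultiParadigmSet, SolverStatus, learn_multigraph
from .pipeline import RunConfig
from .spectral import eigendecompose, gft


def cohort_grid_search(
    config: RunConfig,
    alpha_grid: list[float],
    beta_grid: list[float],
    cutoff_grid: list[int],
    n_folds: int = 10,
    n_repeats: int = 10,
) -> GridSearchResult:
    config.validate()
    paradigms = config.paradigm_names
    subjects = sorted(config.manifest)
    data = {
        s: MultiParadigmSet(
            tuple(
                read_signal_matrix(
                    config.manifest[s][p], transpose=config.transpose_input
                )
                for p in paradigms
            ),
            tuple(paradigms),
        )
        for s in subjects
    }
    labels = [config.groups[s] for s in subjects]
    n = data[subjects[0]].n_nodes
    iu, ju = np.triu_indices(n, 1)
    cache: dict[tuple[float, float], list] = {}

    def learned(alpha: float, beta: float):
        key = (alpha, beta)
        if key not in cache:
            cfg = LearningConfig(beta=beta, alpha=alpha)
            results = []
            for s in subjects:
                res = learn_multigraph(data[s], cfg)
                if res.solver_status == SolverStatus.FAILED:
                    raise RuntimeError(f"solver failed for subject {s}")
                decomps = [eigendecompose(L) for L in res.laplacians]
                coeffs = [
                    gft(data[s].paradigms[k], decomps[k])
                    for k in range(len(paradigms))
                ]
                results.append((res.laplacians, decomps, coeffs))
            cache[key] = results
        return cache[key]

    def feature_builder(alpha: float, beta: float, cutoff: int) -> np.ndarray:
        rows = []
        for laps, _, coeffs in learned(alpha, beta):
            lap_feats = np.concatenate([L.matrix[iu, ju] for L in laps])
            energy_feats = np.concatenate(
                [
                    projection_energy(c, (1, min(cutoff, n))).per_basis_energy[:cutoff]
                    for c in coeffs
                ]
            )
            rows.append(np.concatenate([lap_feats, energy_feats]))
        return np.array(rows)

    return grid_search(
        feature_builder,
        labels,
        alpha_grid,
        beta_grid,
        cutoff_grid,
        seed=config.seed,
        n_folds=n_folds,
        n_repeats=n_repeats,
    )
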