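"""Low-frequency projection energy and hub-region detection.

The projection energy of eigenbasis ``i`` is the summed squared GFT
coefficient of that basis across observations.  Hub detection proceeds in
two thresholding passes with the same mean + 2 SD rule: first spike
eigenbases are selected on the (group-averaged, area-normalized) low-band
energy spectrum; then each selected basis's energy is attributed to nodes
through the squared eigenvector entries, and nodes whose attributed score
exceeds mean + 2 SD across nodes are reported as hubs.  Squared entries make
the node scores invariant to basis rotations inside degenerate eigenspaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import SpectralDecomposition, SpectrumCoefficients


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-eigenbasis projection energy (length n; zero outside the band)."""

    per_basis_energy: np.ndarray
    band: tuple[int, int]  # 1-based inclusive (lo, hi)
    normalized: bool = False
    n_subjects_averaged: int = 1

    def __post_init__(self) -> None:
        e = np.asarray(self.per_basis_energy, dtype=float)
        if np.any(e < 0):
            raise ValueError("energies must be nonnegative")
        object.__setattr__(self, "per_basis_energy", e)

    def band_values(self) -> np.ndarray:
        lo, hi = self.band
        return self.per_basis_energy[lo - 1 : hi]


@dataclass(frozen=True)
class HubReport:
    selected_bases: tuple[int, ...]  # 1-based eigenbasis indices
    node_scores: np.ndarray
    hub_nodes: tuple[int, ...]  # 0-based node indices
    threshold_used: float
    node_labels: tuple[str, ...] | None = None


def projection_energy(
    coeffs: SpectrumCoefficients, band: tuple[int, int]
) -> EnergySpectrum:
    """Energy ``sum_t x~_i(t)^2`` for each eigenbasis i in the 1-based
    inclusive index range ``band``; zero outside."""
    n = coeffs.coefficients.shape[0]
    lo, hi = band
    if not 1 <= lo <= hi <= n:
        raise ValueError(f"band {band} out of range [1, {n}]")
    energy = np.zeros(n)
    energy[lo - 1 : hi] = np.sum(coeffs.coefficients[lo - 1 : hi] ** 2, axis=1)
    return EnergySpectrum(energy, band)


def normalize_spectrum(spectrum: EnergySpectrum) -> EnergySpectrum:
    """Scale to unit total energy (unit area under the curve); idempotent."""
    total = spectrum.per_basis_energy.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return EnergySpectrum(
        spectrum.per_basis_energy / total,
        spectrum.band,
        normalized=True,
        n_subjects_averaged=spectrum.n_subjects_averaged,
    )


def group_average_spectrum(
    spectra: list[EnergySpectrum],
    exclude_first: bool = False,
    normalize_each: bool = False,
) -> EnergySpectrum:
    """Elementwise mean of per-subject spectra, normalized to unit area.

    ``exclude_first`` zeroes the first eigenbasis (the constant eigenvector,
    which carries the uninformative mean component) before normalization.
    ``normalize_each`` normalizes every subject spectrum before averaging;
    the default normalizes only the averaged curve.
    """
    if not spectra:
        raise ValueError("empty spectrum list")
    lengths = {s.per_basis_energy.size for s in spectra}
    if len(lengths) != 1:
        raise ValueError("spectra have mismatched lengths")
    band = spectra[0].band
    stack = [
        normalize_spectrum(s).per_basis_energy if normalize_each else s.per_basis_energy
        for s in spectra
    ]
    mean = np.mean(stack, axis=0)
    lo, hi = band
    if exclude_first:
        mean = mean.copy()
        mean[0] = 0.0
        lo = max(lo, 2)
    avg = EnergySpectrum(mean, (lo, hi), n_subjects_averaged=len(spectra))
    return normalize_spectrum(avg)


def select_spike_bases(spectrum: EnergySpectrum) -> list[int]:
    """1-based indices of eigenbases whose band energy exceeds mean + 2 SD.

    Mean and SD are computed over the band entries only; a flat spectrum
    selects nothing (SD = 0, strict inequality).
    """
    vals = spectrum.band_values()
    if vals.size < 2:
        raise ValueError("band must contain at least 2 eigenbases")
    thr = vals.mean() + 2.0 * vals.std(ddof=1)
    lo = spectrum.band[0]
    return [int(i) + lo for i in np.flatnonzero(vals > thr)]


def _node_scores_one_subject(
    selected: list[int], decomp: SpectralDecomposition, energy: EnergySpectrum
) -> np.ndarray:
    F = decomp.eigenvectors
    idx = np.asarray(selected, dtype=int) - 1
    return (F[:, idx] ** 2) @ energy.per_basis_energy[idx]


def map_bases_to_nodes(
    selected: list[int],
    decomps: list[SpectralDecomposition],
    energies: list[EnergySpectrum],
    node_labels: list[str] | None = None,
) -> HubReport:
    """Attribute selected-basis energy to nodes and threshold for hubs.

    Node score = across-subject mean of ``sum_{i in selected}
    energy_i * f_i(v)^2``; hubs are nodes with score strictly above
    mean + 2 SD across nodes (the same rule as the basis selection).
    """
    if not selected:
        raise ValueError("no eigenbases selected")
    if len(decomps) != len(energies):
        raise ValueError("mismatched subject lists")
    scores = np.mean(
        [_node_scores_one_subject(selected, d, e) for d, e in zip(decomps, energies)],
        axis=0,
    )
    thr = float(scores.mean() + 2.0 * scores.std(ddof=1))
    hubs = tuple(int(v) for v in np.flatnonzero(scores > thr))
    return HubReport(
        tuple(selected), scores, hubs, thr,
        tuple(node_labels) if node_labels is not None else None,
    )


def subject_node_scores(
    selected: list[int],
    decomps: list[SpectralDecomposition],
    energies: list[EnergySpectrum],
) -> np.ndarray:
    """Per-subject node-score matrix (subjects x nodes), for group tests."""
    return np.array(
        [_node_scores_one_subject(selected, d, e) for d, e in zip(decomps, energies)]
    )


def group_difference_test(
    node_scores_group_a: np.ndarray,
    node_scores_group_b: np.ndarray,
    nodes: list[int] | None = None,
    correct: bool = False,
) -> dict[int, float]:
    """Welch two-sample t-test per node on subject-level hub scores.

    Returns raw p-values by default (Benjamini-Hochberg optional via
    ``correct=True``).  A node with zero variance in both groups gets NaN.
    """
    a = np.atleast_2d(np.asarray(node_scores_group_a, dtype=float))
    b = np.atleast_2d(np.asarray(node_scores_group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if nodes is None:
        nodes = list(range(a.shape[1]))
    pvals = {}
    for v in nodes:
        xa, xb = a[:, v], b[:, v]
        if xa.std() == 0.0 and xb.std() == 0.0:
            pvals[int(v)] = 1.0 if np.isclose(xa.mean(), xb.mean()) else np.nan
            continue
        pvals[int(v)] = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    if correct:
        keys = list(pvals)
        raw = np.array([pvals[k] for k in keys])
        ok = ~np.isnan(raw)
        adj = raw.copy()
        adj[ok] = stats.false_discovery_control(raw[ok])
        pvals = {k: float(p) for k, p in zip(keys, adj)}
    return pvals
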