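"""Univariate Wilks' λ feature selection for spectral variables.

For each wavenumber j, λ_j = SS_within,j / SS_total,j from the one-way ANOVA
decomposition SS_total = SS_within + SS_between.  Small λ means class means
differ by more than the within-class spread, so the variable discriminates.
Variables with λ strictly below a threshold (0.5 by convention, relaxed to
0.75 when nothing passes) are retained, and maximal runs of adjacent selected
grid points are reported as cm⁻¹ regions in the descending "high~low"
notation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_spectra import SpectralDataset, WavenumberGrid

__all__ = ["WilksResult", "wilks_lambda", "select_variables", "format_regions"]


@dataclass
class WilksResult:
    lambda_per_variable: np.ndarray
    threshold: float
    selected_indices: np.ndarray
    selected_regions: list[tuple[float, float]]

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)


def wilks_lambda(X: np.ndarray, labels) -> np.ndarray:
    """Per-variable Wilks' λ = within-class SS / total SS, each in [0, 1].

    Constant variables (zero total SS) are assigned λ = 1: with no variance at
    all they carry no between-class information.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("Wilks' lambda needs at least 2 classes")
    if (counts < 2).any():
        bad = classes[counts < 2].tolist()
        raise ValueError(f"every class needs >= 2 spectra; singletons: {bad}")
    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum(axis=0)
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[labels == c]
        ss_within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    lam = np.ones(X.shape[1])
    nz = ss_total > 0
    lam[nz] = ss_within[nz] / ss_total[nz]
    return np.clip(lam, 0.0, 1.0)


def select_variables(
    lam: np.ndarray, threshold: float, grid: WavenumberGrid
) -> WilksResult:
    """Select variables with λ strictly below ``threshold``; group into regions.

    Regions are maximal runs of adjacent selected grid points, reported as
    (high_cm1, low_cm1) pairs.  An empty selection is returned with a warning
    so the caller may escalate the threshold.
    """
    lam = np.asarray(lam, dtype=float)
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if lam.size != grid.n_points:
        raise ValueError("lambda vector length must match the grid")
    selected = np.flatnonzero(lam < threshold)
    if selected.size == 0:
        warnings.warn(
            f"no variable has Wilks' lambda < {threshold}; consider raising the threshold"
        )
        return WilksResult(lam, threshold, selected, [])
    values = grid.values
    regions = []
    run_start = selected[0]
    prev = selected[0]
    for j in selected[1:]:
        if j != prev + 1:
            regions.append((float(values[run_start]), float(values[prev])))
            run_start = j
        prev = j
    regions.append((float(values[run_start]), float(values[prev])))
    return WilksResult(lam, threshold, selected, regions)


def format_regions(result: WilksResult) -> str:
    """Regions in the conventional descending notation, e.g. '1765~1726 cm⁻¹'."""
    return ", ".join(f"{hi:g}~{lo:g} cm-1" for hi, lo in result.selected_regions)


def wilks_select(
    dataset: SpectralDataset, labels, threshold: float = 0.5
) -> WilksResult:
    """Convenience: compute λ on a dataset and threshold it in one call."""
    lam = wilks_lambda(dataset.intensities, labels)
    return select_variables(lam, threshold, dataset.grid)
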