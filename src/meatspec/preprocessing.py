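"""Spectral preprocessing: baseline, derivative, cropping, outliers, scaling.

The pipeline mirrors common FT-IR practice for biological fingerprints:

1. asymmetric-least-squares (AsLS) baseline estimation and subtraction,
2. optional Savitzky–Golay second derivative,
3. cropping to the fingerprint region (default 1800–1000 cm⁻¹, 801 points on
   a 1 cm⁻¹ grid),
4. Mahalanobis-on-PCA-scores outlier flagging within each class,
5. one of three scaling modes (none, mean-centre, auto-scale) whose state is
   fitted on calibration data only and re-applied verbatim to new data.

"Original spectra" throughout the package means baseline-corrected, cropped,
underivatised absorbance — the default input to every model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .synthetic_spectra import SpectralDataset, WavenumberGrid

__all__ = [
    "PreprocessSpec",
    "ScalerState",
    "asls_baseline",
    "baseline_correct",
    "savgol_second_derivative",
    "crop_fingerprint",
    "detect_outliers",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "apply_preprocessing",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Declarative description of the preprocessing chain.

    AsLS parameters: ``asls_lam`` controls baseline stiffness (larger =
    smoother), ``asls_p`` the asymmetry (weight of points above the baseline).
    """

    baseline: str = "asls"  # none | asls
    asls_lam: float = 1e7
    asls_p: float = 0.01
    asls_niter: int = 10
    derivative: str = "none"  # none | savgol2
    savgol_window: int = 9
    savgol_polyorder: int = 3
    crop: tuple[float, float] = (1800.0, 1000.0)
    scaling: str = "none"  # none | mean_center | auto_scale

    def __post_init__(self) -> None:
        if self.baseline not in ("none", "asls"):
            raise ValueError(f"unknown baseline mode {self.baseline!r}")
        if self.derivative not in ("none", "savgol2"):
            raise ValueError(f"unknown derivative mode {self.derivative!r}")
        if self.scaling not in ("none", "mean_center", "auto_scale"):
            raise ValueError(f"unknown scaling mode {self.scaling!r}")
        if self.derivative == "savgol2":
            if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_polyorder:
                raise ValueError("savgol window must be odd and exceed polyorder")
        if self.crop is not None and len(self.crop) != 2:
            raise ValueError("crop must be a (high, low) cm-1 pair or None")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crop"] = list(self.crop) if self.crop is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PreprocessSpec keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("crop") is not None:
            d["crop"] = tuple(d["crop"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessSpec":
        return cls.from_dict(yaml.safe_load(text) or {})


# ---------------------------------------------------------------------------
# AsLS baseline


def _asls_penalty_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form (bandwidth 2) of lam * D2'D2, D2 = second difference."""
    ab = np.zeros((3, n))
    ab[0, 2:] = lam                       # second superdiagonal
    ab[1, 1:] = -4.0 * lam                # first superdiagonal
    ab[1, 1] = -2.0 * lam
    ab[1, -1] = -2.0 * lam
    ab[2, :] = 6.0 * lam                  # diagonal
    ab[2, 0] = lam
    ab[2, -1] = lam
    ab[2, 1] = 5.0 * lam
    ab[2, -2] = 5.0 * lam
    return ab


def asls_baseline(
    y: np.ndarray, lam: float = 1e7, p: float = 0.01, niter: int = 10
) -> tuple[np.ndarray, bool]:
    """Asymmetric least squares baseline of one spectrum.

    Returns ``(baseline, converged)`` where convergence means the asymmetric
    weights stopped changing before ``niter`` was exhausted.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    base = _asls_penalty_banded(n, lam)
    w = np.ones(n)
    z = y
    converged = False
    for _ in range(niter):
        ab = base.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            converged = True
            break
        w = w_new
    return z, converged


def baseline_correct(dataset: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    """Estimate and subtract a smooth per-spectrum baseline.

    Adds a boolean ``baseline_converged`` metadata column; non-convergence is
    flagged, never fatal.
    """
    if spec.baseline == "none":
        out = dataset.with_intensities(dataset.intensities.copy())
        out.meta["baseline_converged"] = True
        return out
    X = dataset.intensities
    corrected = np.empty_like(X)
    flags = np.empty(X.shape[0], dtype=bool)
    for i in range(X.shape[0]):
        z, ok = asls_baseline(X[i], lam=spec.asls_lam, p=spec.asls_p, niter=spec.asls_niter)
        corrected[i] = X[i] - z
        flags[i] = ok
    out = dataset.with_intensities(corrected)
    out.meta["baseline_converged"] = flags
    return out


def savgol_second_derivative(
    dataset: SpectralDataset, window: int = 9, polyorder: int = 3
) -> SpectralDataset:
    """Savitzky–Golay 2nd derivative along the wavenumber axis.

    Edge points come from the polynomial fitted on the one-sided window
    (scipy ``mode='interp'``).  The derivative is taken with respect to cm⁻¹,
    so it is independent of the grid's descending storage order.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    if polyorder < 2:
        raise ValueError("polyorder must be >= 2 for a second derivative")
    if window > dataset.grid.n_points:
        raise ValueError("window exceeds number of grid points")
    deriv = savgol_filter(
        dataset.intensities,
        window_length=window,
        polyorder=polyorder,
        deriv=2,
        delta=dataset.grid.step_cm1,
        axis=1,
        mode="interp",
    )
    return dataset.with_intensities(deriv)


def crop_fingerprint(
    dataset: SpectralDataset, interval: tuple[float, float] = (1800.0, 1000.0)
) -> SpectralDataset:
    """Restrict variables to a closed cm⁻¹ interval (order-insensitive)."""
    mask = dataset.grid.interval_mask(interval)
    if not mask.any():
        raise ValueError(f"crop interval {interval} does not intersect the grid")
    idx = np.flatnonzero(mask)
    vals = dataset.grid.values[idx]
    grid = WavenumberGrid(start_cm1=float(vals[0]), end_cm1=float(vals[-1]), n_points=len(vals))
    return dataset.with_intensities(dataset.intensities[:, idx].copy(), grid=grid)


def detect_outliers(
    dataset: SpectralDataset,
    n_pcs: int = 3,
    cutoff: float = 3.0,
    per_class: bool = True,
) -> np.ndarray:
    """Flag spectra whose PCA-score Mahalanobis distance exceeds ``cutoff``.

    Scores are the first ``n_pcs`` principal components computed within each
    class (or globally when ``per_class`` is False); the distance is measured
    to the class centroid using the diagonal score covariance.  Classes too
    small to support the requested components are skipped with a warning.
    """
    X = dataset.intensities
    labels = dataset.meta["class_name"].to_numpy()
    flags = np.zeros(X.shape[0], dtype=bool)
    if per_class:
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    else:
        groups = [np.arange(X.shape[0])]
    for idx in groups:
        if len(idx) < n_pcs + 2:
            warnings.warn(
                f"class with {len(idx)} spectra skipped in outlier detection "
                f"(needs > {n_pcs + 1})"
            )
            continue
        Xi = X[idx] - X[idx].mean(axis=0)
        _, s, Vt = np.linalg.svd(Xi, full_matrices=False)
        T = Xi @ Vt[:n_pcs].T
        var = (s[:n_pcs] ** 2) / (len(idx) - 1)
        var = np.maximum(var, 1e-30)
        d = np.sqrt((T**2 / var).sum(axis=1))
        flags[idx] = d > cutoff
    return flags


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalerState:
    """Frozen per-variable mean/scale fitted on calibration data only."""

    mode: str
    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray

    def n_constant(self) -> int:
        return int(self.constant_mask.sum())


def fit_scaler(X: np.ndarray, mode: str) -> ScalerState:
    if mode not in ("none", "mean_center", "auto_scale"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = sd <= 1e-15
    if mode == "none":
        return ScalerState(mode, np.zeros(X.shape[1]), np.ones(X.shape[1]), constant)
    if mode == "mean_center":
        return ScalerState(mode, mean, np.ones(X.shape[1]), constant)
    scale = np.where(constant, 1.0, sd)  # constant variables flagged, scale 1
    return ScalerState(mode, mean, scale, constant)


def apply_scaler(X: np.ndarray, state: ScalerState) -> np.ndarray:
    return (np.asarray(X, dtype=float) - state.mean) / state.scale


def invert_scaler(Xs: np.ndarray, state: ScalerState) -> np.ndarray:
    return np.asarray(Xs, dtype=float) * state.scale + state.mean


def apply_preprocessing(dataset: SpectralDataset, spec: PreprocessSpec) -> SpectralDataset:
    """Baseline → derivative → crop (scaling is model-side, fitted on folds)."""
    out = baseline_correct(dataset, spec)
    if spec.derivative == "savgol2":
        out = savgol_second_derivative(out, spec.savgol_window, spec.savgol_polyorder)
    if spec.crop is not None:
        out = crop_fingerprint(out, tuple(spec.crop))
    return out
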