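"""PLS regression of offal mass fraction on spectra (PLS1 via NIPALS).

One continuous response (the w/w adulterant fraction) is regressed on the
fingerprint spectrum.  PLS1 with explicit deflation is used; X and y are
always mean-centred internally (auto-scaling optional), and the centring /
scaling state travels with the model so prediction data are treated exactly
like calibration data.

Predictions are reported both raw and clamped to [0, 1]; the physical mass
fraction cannot leave that interval, but the raw value is diagnostic (a
strongly negative raw prediction flags an off-model spectrum).  A prediction
outside the training fraction range ± 0.1 is flagged as extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import ScalerState, apply_scaler, fit_scaler
from .validation import kfold_indices

__all__ = ["PLSRegressor", "QuantPrediction", "select_n_lv"]


@dataclass
class QuantPrediction:
    raw_fraction: np.ndarray
    clamped_fraction: np.ndarray
    extrapolated: np.ndarray
    model_id: str


class PLSRegressor:
    """PLS1 regression with NIPALS deflation.

    Parameters
    ----------
    n_lv:
        Number of latent variables.
    scaling:
        "mean_center" (default) or "auto_scale".  Centring always happens;
        auto-scaling additionally divides by the calibration standard
        deviation of each variable.
    """

    def __init__(self, n_lv: int, scaling: str = "mean_center", selection=None, model_id: str = "plsr"):
        if scaling not in ("none", "mean_center", "auto_scale"):
            raise ValueError(f"unknown scaling mode {scaling!r}")
        self.n_lv = int(n_lv)
        # "none" and "mean_center" coincide: PLS is fitted on centred data
        self.scaling = scaling
        self.selection = None if selection is None else np.asarray(selection, dtype=int)
        self.model_id = model_id

    # -- fitting -----------------------------------------------------------

    def _slice(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X if self.selection is None else X[:, self.selection]

    def fit(self, X, y) -> "PLSRegressor":
        X = self._slice(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if np.ptp(y) == 0:
            raise ValueError("constant response: nothing to regress")
        if self.n_lv < 1 or self.n_lv > min(X.shape):
            raise ValueError("n_lv must satisfy 1 <= n_lv <= rank bound of X")
        mode = "auto_scale" if self.scaling == "auto_scale" else "none"
        self.scaler_ = fit_scaler(X, mode)
        Xs = apply_scaler(X, self.scaler_)
        self.x_mean_ = Xs.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xd = Xs - self.x_mean_
        yd = y - self.y_mean_
        ss_x_total = float((Xd**2).sum())
        ss_y_total = float((yd**2).sum())

        n, p = Xd.shape
        W = np.zeros((p, self.n_lv))
        P = np.zeros((p, self.n_lv))
        b = np.zeros(self.n_lv)
        self.x_variance_explained_ = np.zeros(self.n_lv)
        self.y_variance_explained_ = np.zeros(self.n_lv)
        ss_x_prev, ss_y_prev = ss_x_total, ss_y_total
        for a in range(self.n_lv):
            w = Xd.T @ yd
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"PLS broke down at component {a + 1} (zero covariance)")
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValueError(f"PLS broke down at component {a + 1} (zero scores)")
            p_load = Xd.T @ t / tt
            b_a = float(yd @ t / tt)
            Xd = Xd - np.outer(t, p_load)
            yd = yd - b_a * t
            W[:, a], P[:, a], b[a] = w, p_load, b_a
            ss_x = float((Xd**2).sum())
            ss_y = float((yd**2).sum())
            self.x_variance_explained_[a] = (ss_x_prev - ss_x) / ss_x_total if ss_x_total else 0.0
            self.y_variance_explained_[a] = (ss_y_prev - ss_y) / ss_y_total if ss_y_total else 0.0
            ss_x_prev, ss_y_prev = ss_x, ss_y
        self.weights_, self.loadings_, self.b_ = W, P, b
        # coefficients for every truncation 1..n_lv (cheap, reused by CV)
        R = W @ np.linalg.inv(np.triu(P.T @ W))
        self.coef_path_ = np.cumsum(R * b[None, :], axis=1)
        self.coef_ = self.coef_path_[:, -1]
        self.train_fraction_range_ = (float(y.min()), float(y.max()))
        return self

    # -- prediction --------------------------------------------------------

    def _raw_predict(self, X, n_lv: int | None = None) -> np.ndarray:
        Xs = apply_scaler(self._slice(X), self.scaler_)
        coef = self.coef_ if n_lv is None else self.coef_path_[:, n_lv - 1]
        return (Xs - self.x_mean_) @ coef + self.y_mean_

    def predict(self, X) -> QuantPrediction:
        raw = self._raw_predict(X)
        lo, hi = self.train_fraction_range_
        return QuantPrediction(
            raw_fraction=raw,
            clamped_fraction=np.clip(raw, 0.0, 1.0),
            extrapolated=(raw < lo - 0.1) | (raw > hi + 0.1),
            model_id=self.model_id,
        )

    def predict_components(self, X) -> np.ndarray:
        """Raw predictions for every component count 1..n_lv (n × n_lv)."""
        Xs = apply_scaler(self._slice(X), self.scaler_)
        return (Xs - self.x_mean_) @ self.coef_path_ + self.y_mean_


def select_n_lv(
    X,
    y,
    max_lv: int = 15,
    folds: int = 5,
    seed: int = 0,
    groups=None,
    scaling: str = "mean_center",
) -> tuple[int, np.ndarray]:
    """Choose the PLSR component count by k-fold RMSECV with a one-SE rule.

    Returns ``(n_lv, rmsecv)`` where ``rmsecv[a-1]`` is the cross-validated
    RMSE with ``a`` components.  Among component counts, the smallest one
    whose RMSECV is within one standard error of the minimum is selected
    (parsimony bias toward fewer components).  Deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    max_lv = int(min(max_lv, min(X.shape) - 1))
    strata = np.array([f"{v:.4f}" for v in y])  # stratify folds by response level
    fold = kfold_indices(strata, folds, seed=seed, groups=groups)
    sq_err = np.zeros((folds, max_lv))
    counts = np.zeros(folds)
    for f in range(folds):
        test = fold == f
        model = PLSRegressor(n_lv=max_lv, scaling=scaling).fit(X[~test], y[~test])
        pred = model.predict_components(X[test])
        sq_err[f] = ((pred - y[test, None]) ** 2).sum(axis=0)
        counts[f] = test.sum()
    rmsecv = np.sqrt(sq_err.sum(axis=0) / counts.sum())
    per_fold_rmse = np.sqrt(sq_err / counts[:, None])
    se = per_fold_rmse.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(rmsecv))
    threshold = rmsecv[best] + se[best] + 1e-12
    n_lv = int(np.flatnonzero(rmsecv <= threshold)[0]) + 1
    return n_lv, rmsecv
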