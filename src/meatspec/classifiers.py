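"""Five classifier families with a uniform fit/predict contract.

All models are implemented from first principles on numpy/scipy linear
algebra (no external ML dependency): canonical-variate LDA, PCA-DA, PLS-DA
via NIPALS, k-nearest neighbours, and SIMCA class modelling.  Every model

* accepts a scaling mode (none / mean_center / auto_scale) whose state is
  fitted during ``fit`` and re-applied verbatim in ``predict`` — train/test
  preprocessing symmetry is structural, not a convention;
* optionally restricts itself to a variable selection (e.g. Wilks' λ
  indices), stored with the model;
* breaks ties deterministically, alphabetically by class label.

Class labels are kept in sorted (alphabetical) order everywhere, which makes
argmax/argmin tie-breaking alphabetical for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .preprocessing import ScalerState, apply_scaler, fit_scaler

__all__ = [
    "LinearDiscriminantClassifier",
    "PCADiscriminantClassifier",
    "PLSDiscriminantClassifier",
    "KNearestClassifier",
    "SIMCAClassifier",
]


def _prepare_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.array(sorted(np.unique(y).tolist()))
    return y, classes


class _SpectralModel:
    """Shared plumbing: variable selection + scaler symmetry."""

    def __init__(self, scaling: str = "none", selection: np.ndarray | None = None):
        self.scaling = scaling
        self.selection = None if selection is None else np.asarray(selection, dtype=int)
        self.scaler_: ScalerState | None = None

    def _fit_prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.selection is not None:
            X = X[:, self.selection]
        self.n_vars_in_ = X.shape[1]
        self.scaler_ = fit_scaler(X, self.scaling)
        return apply_scaler(X, self.scaler_)

    def _predict_prepare(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.selection is not None:
            if X.shape[1] <= self.selection.max():
                raise ValueError(
                    f"input has {X.shape[1]} variables; selection expects at "
                    f"least {self.selection.max() + 1}"
                )
            X = X[:, self.selection]
        if X.shape[1] != self.n_vars_in_:
            raise ValueError(
                f"input has {X.shape[1]} variables, model was fitted on {self.n_vars_in_}"
            )
        return apply_scaler(X, self.scaler_)


# ---------------------------------------------------------------------------
# LDA


class LinearDiscriminantClassifier(_SpectralModel):
    """Canonical-variate LDA with Mahalanobis-to-centroid assignment.

    Canonical directions solve the generalised eigenproblem of between-class
    scatter against ridge-regularised pooled within-class scatter; exactly
    ``n_classes - 1`` canonical variables are kept, ordered by descending
    between/within variance ratio.

    Assignment measures the Mahalanobis distance to each class centroid in
    canonical space.  By default each class uses its own canonical-space
    covariance (shrunk toward the pooled one for stability): adulteration
    classes stretch along the dilution direction while authentic meat stays
    compact, and a shared pooled metric would hand every low-fraction mixture
    to the tight meat class.  ``covariance="pooled"`` restores the classical
    Fisher rule.  Equal priors; ties break alphabetically.
    """

    def __init__(
        self,
        scaling: str = "none",
        selection=None,
        ridge: float | None = None,
        covariance: str = "pooled",
        shrinkage: float = 0.1,
    ):
        super().__init__(scaling, selection)
        if covariance not in ("per_class", "pooled"):
            raise ValueError(f"unknown covariance mode {covariance!r}")
        self.ridge = ridge
        self.covariance = covariance
        self.shrinkage = shrinkage

    def fit(self, X, y) -> "LinearDiscriminantClassifier":
        Xs = self._fit_prepare(X)
        y, classes = _prepare_labels(y)
        n, p = Xs.shape
        if classes.size < 2:
            raise ValueError("LDA needs at least 2 classes")
        if p >= n:
            raise ValueError(
                f"LDA requires fewer variables ({p}) than spectra ({n}); "
                "reduce dimensionality first, e.g. with Wilks' lambda selection"
            )
        grand = Xs.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        means = {}
        for c in classes:
            Xc = Xs[y == c]
            if len(Xc) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 spectra")
            mc = Xc.mean(axis=0)
            means[c] = mc
            D = Xc - mc
            Sw += D.T @ D
            d = (mc - grand)[:, None]
            Sb += len(Xc) * (d @ d.T)
        gamma = self.ridge if self.ridge is not None else 1e-6 * np.trace(Sw) / p
        Sw_reg = Sw + gamma * np.eye(p)
        evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
        order = np.argsort(evals)[::-1][: classes.size - 1]
        self.classes_ = classes
        self.eigenvalues_ = evals[order]
        self.loadings_ = evecs[:, order]          # p x (g-1), Sw-orthonormal
        self.grand_mean_ = grand
        self.centroids_ = np.vstack([(means[c] - grand) @ self.loadings_ for c in classes])
        self.n_samples_ = n
        # canonical-space covariances: pooled is ~identity/(n-g) by the
        # Sw-orthonormality of the loadings; per-class ones are estimated
        # from the canonical scores and shrunk toward pooled
        T_all = (Xs - grand) @ self.loadings_
        a = T_all.shape[1]
        pooled = np.zeros((a, a))
        for c in classes:
            Tc = T_all[y == c] - (means[c] - grand) @ self.loadings_
            pooled += Tc.T @ Tc
        pooled /= max(n - classes.size, 1)
        self.class_cov_inv_ = {}
        self.class_cov_logdet_ = {}
        for c in classes:
            in_c = y == c
            Tc = T_all[in_c] - (means[c] - grand) @ self.loadings_
            if self.covariance == "per_class":
                cov_c = (Tc.T @ Tc) / max(len(Tc) - 1, 1)
                cov_c = (1.0 - self.shrinkage) * cov_c + self.shrinkage * pooled
            else:
                cov_c = pooled
            cov_c = cov_c + 1e-12 * np.trace(pooled) / a * np.eye(a)
            self.class_cov_inv_[c] = np.linalg.inv(cov_c)
            self.class_cov_logdet_[c] = float(np.linalg.slogdet(cov_c)[1])
        return self

    def transform(self, X) -> np.ndarray:
        Xs = self._predict_prepare(X)
        return (Xs - self.grand_mean_) @ self.loadings_

    def distances(self, X) -> np.ndarray:
        """Mahalanobis distance to each class centroid in canonical space."""
        T = self.transform(X)
        out = np.empty((len(T), len(self.classes_)))
        for k, c in enumerate(self.classes_):
            diff = T - self.centroids_[k]
            out[:, k] = np.sqrt(np.einsum("ij,jk,ik->i", diff, self.class_cov_inv_[c], diff))
        return out

    def predict(self, X) -> np.ndarray:
        d = self.distances(X)
        return self.classes_[np.argmin(d, axis=1)]


# ---------------------------------------------------------------------------
# PCA helper (shared by PCA-DA and SIMCA)


@dataclass
class _PCAState:
    mean: np.ndarray
    loadings: np.ndarray        # p x a
    singular_values: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.loadings


def _fit_pca(X: np.ndarray, n_pcs: int) -> _PCAState:
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return _PCAState(mean=mean, loadings=Vt[:n_pcs].T, singular_values=s[:n_pcs])


class PCADiscriminantClassifier(_SpectralModel):
    """PCA for dimension reduction, then canonical-variate LDA on the scores."""

    def __init__(self, n_pcs: int, scaling: str = "auto_scale", selection=None):
        super().__init__(scaling, selection)
        self.n_pcs = int(n_pcs)

    def fit(self, X, y) -> "PCADiscriminantClassifier":
        Xs = self._fit_prepare(X)
        if self.n_pcs >= Xs.shape[0]:
            raise ValueError("n_pcs must be smaller than the number of calibration spectra")
        if self.n_pcs > min(Xs.shape):
            raise ValueError("n_pcs exceeds the rank bound of the calibration matrix")
        self.pca_ = _fit_pca(Xs, self.n_pcs)
        self.lda_ = LinearDiscriminantClassifier(scaling="none").fit(self.pca_.scores(Xs), y)
        self.classes_ = self.lda_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        Xs = self._predict_prepare(X)
        return self.lda_.predict(self.pca_.scores(Xs))


# ---------------------------------------------------------------------------
# PLS-DA


def _nipals_pls2(
    X: np.ndarray, Y: np.ndarray, n_lv: int, max_iter: int = 1000, tol: float = 1e-8
):
    """PLS2 NIPALS with deflation.  Returns W, P, C, T (columns per component).

    The score iteration starts from the response column with maximal variance
    so the fit is deterministic.
    """
    n, p = X.shape
    q = Y.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    C = np.zeros((q, n_lv))
    T = np.zeros((n, n_lv))
    Xd, Yd = X.copy(), Y.copy()
    for a in range(n_lv):
        u = Yd[:, np.argmax(Yd.var(axis=0))]
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError(f"NIPALS broke down at component {a + 1} (zero weight)")
            w /= norm
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise ValueError(f"NIPALS failed to converge at component {a + 1}")
        p_load = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_load, c, t
    return W, P, C, T


class PLSDiscriminantClassifier(_SpectralModel):
    """PLS2 against a one-hot class matrix; assignment by argmax response."""

    def __init__(self, n_lv: int, scaling: str = "none", selection=None, max_iter: int = 1000):
        super().__init__(scaling, selection)
        self.n_lv = int(n_lv)
        self.max_iter = max_iter

    def fit(self, X, y) -> "PLSDiscriminantClassifier":
        Xs = self._fit_prepare(X)
        y, classes = _prepare_labels(y)
        if self.n_lv > min(Xs.shape):
            raise ValueError("n_lv exceeds the rank bound of the calibration matrix")
        Y = (y[:, None] == classes[None, :]).astype(float)
        self.x_mean_ = Xs.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc, Yc = Xs - self.x_mean_, Y - self.y_mean_
        W, P, C, T = _nipals_pls2(Xc, Yc, self.n_lv, self.max_iter)
        self.coef_ = W @ np.linalg.solve(P.T @ W, C.T)
        self.scores_ = T
        self.classes_ = classes
        return self

    def decision_values(self, X) -> np.ndarray:
        Xs = self._predict_prepare(X)
        return (Xs - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        # np.argmax returns the first maximum; classes_ is alphabetical
        return self.classes_[np.argmax(self.decision_values(X), axis=1)]


# ---------------------------------------------------------------------------
# KNN


class KNearestClassifier(_SpectralModel):
    """Majority vote among the k nearest calibration spectra.

    Vote ties are broken by the smaller mean distance among the tied classes,
    then alphabetically.
    """

    def __init__(self, k: int = 3, metric: str = "euclidean", scaling: str = "none", selection=None):
        super().__init__(scaling, selection)
        if metric not in ("euclidean", "mahalanobis"):
            raise ValueError(f"unknown metric {metric!r}")
        self.k = int(k)
        self.metric = metric

    def fit(self, X, y) -> "KNearestClassifier":
        Xs = self._fit_prepare(X)
        y, classes = _prepare_labels(y)
        if not 1 <= self.k <= len(Xs):
            raise ValueError("k must satisfy 1 <= k <= n_training")
        self.X_ = Xs
        self.y_ = y
        self.classes_ = classes
        if self.metric == "mahalanobis":
            cov = np.cov(Xs, rowvar=False)
            cov += 1e-6 * np.trace(np.atleast_2d(cov)) / cov.shape[0] * np.eye(cov.shape[0])
            self.vi_ = np.linalg.inv(np.atleast_2d(cov))
        return self

    def _pairwise(self, A: np.ndarray) -> np.ndarray:
        diff = A[:, None, :] - self.X_[None, :, :]
        if self.metric == "euclidean":
            return np.sqrt((diff**2).sum(axis=2))
        return np.sqrt(np.einsum("ijk,kl,ijl->ij", diff, self.vi_, diff))

    def predict(self, X) -> np.ndarray:
        Xs = self._predict_prepare(X)
        D = self._pairwise(Xs)
        out = np.empty(len(Xs), dtype=object)
        for i in range(len(Xs)):
            nn = np.argsort(D[i], kind="stable")[: self.k]
            votes, dists = {}, {}
            for j in nn:
                c = self.y_[j]
                votes[c] = votes.get(c, 0) + 1
                dists.setdefault(c, []).append(D[i, j])
            best = sorted(
                votes,
                key=lambda c: (-votes[c], float(np.mean(dists[c])), c),
            )[0]
            out[i] = best
        return out.astype(self.classes_.dtype)


# ---------------------------------------------------------------------------
# SIMCA


@dataclass
class _ClassPCAModel:
    mean: np.ndarray
    loadings: np.ndarray         # p x a
    score_var: np.ndarray        # a
    q0: float                    # mean calibration residual SS
    t2_0: float                  # mean calibration T^2
    d_crit: float                # accept/reject threshold on reduced distance
    n_pcs: int


class SIMCAClassifier(_SpectralModel):
    """SIMCA: one PCA model per class, combined Q/T² reduced distance.

    For a new spectrum each class model yields an orthogonal residual distance
    Q (normalised by the class calibration mean Q₀) and a score distance T²
    (normalised by its calibration mean); the combined reduced distance is
    ``d_c = sqrt((Q/Q₀)² + (T²/T²₀)²)``.  ``predict`` force-assigns to the
    class of minimal d_c (single-label confusion tables); ``accepts`` retains
    the classic class-modelling accept/reject output using a per-class
    calibration-percentile threshold.

    ``n_pcs`` may be a single int or a {class: int} mapping (component counts
    are routinely tuned per class).  A requested count is clamped to the
    effective rank of the class submatrix; a class with fewer than 3 spectra
    or zero variance is an error naming the class.
    """

    def __init__(self, n_pcs, scaling: str = "mean_center", selection=None, accept_percentile: float = 97.5):
        super().__init__(scaling, selection)
        self.n_pcs = n_pcs
        self.accept_percentile = accept_percentile

    def _n_pcs_for(self, c: str) -> int:
        if isinstance(self.n_pcs, dict):
            if c not in self.n_pcs:
                raise ValueError(f"no component count given for class {c!r}")
            return int(self.n_pcs[c])
        return int(self.n_pcs)

    def fit(self, X, y) -> "SIMCAClassifier":
        Xs = self._fit_prepare(X)
        y, classes = _prepare_labels(y)
        self.classes_ = classes
        self.models_: dict[str, _ClassPCAModel] = {}
        eps = 1e-12
        for c in classes:
            Xc = Xs[y == c]
            a_req = self._n_pcs_for(c)
            if len(Xc) < 3:
                raise ValueError(f"class {c!r} has too few spectra ({len(Xc)}) for SIMCA")
            if a_req >= len(Xc):
                raise ValueError(
                    f"class {c!r}: n_pcs ({a_req}) must be smaller than the class size ({len(Xc)})"
                )
            mean = Xc.mean(axis=0)
            Xcc = Xc - mean
            _, s, Vt = np.linalg.svd(Xcc, full_matrices=False)
            total = float((s**2).sum())
            if total <= eps:
                raise ValueError(f"class {c!r} has degenerate (zero) covariance")
            rank = int((s > 1e-10 * s[0]).sum())
            a = min(a_req, rank)
            V = Vt[:a].T
            T = Xcc @ V
            score_var = np.maximum((s[:a] ** 2) / max(len(Xc) - 1, 1), eps)
            resid = Xcc - T @ V.T
            q = (resid**2).sum(axis=1)
            q0 = max(float(q.mean()), eps)
            t2 = (T**2 / score_var).sum(axis=1)
            t2_0 = max(float(t2.mean()), eps)
            d_cal = np.sqrt((q / q0) ** 2 + (t2 / t2_0) ** 2)
            d_crit = float(np.percentile(d_cal, self.accept_percentile))
            self.models_[c] = _ClassPCAModel(mean, V, score_var, q0, t2_0, max(d_crit, eps), a)
        return self

    def class_distances(self, X) -> np.ndarray:
        """Reduced distance of each spectrum to each class model (n × g)."""
        Xs = self._predict_prepare(X)
        out = np.empty((len(Xs), len(self.classes_)))
        for k, c in enumerate(self.classes_):
            m = self.models_[c]
            E = Xs - m.mean
            T = E @ m.loadings
            resid = E - T @ m.loadings.T
            q = (resid**2).sum(axis=1)
            t2 = (T**2 / m.score_var).sum(axis=1)
            out[:, k] = np.sqrt((q / m.q0) ** 2 + (t2 / m.t2_0) ** 2)
        return out

    def predict(self, X) -> np.ndarray:
        d = self.class_distances(X)
        return self.classes_[np.argmin(d, axis=1)]

    def accepts(self, X) -> np.ndarray:
        """Boolean membership matrix (n × g): d_c within the class threshold."""
        d = self.class_distances(X)
        crit = np.array([self.models_[c].d_crit for c in self.classes_])
        return d <= crit[None, :]
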