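"""Calibration/prediction split, cross-validation folds, and metric suites.

Splitting follows the study design convention for mixture experiments: the
calibration set holds four of the five biological replicates of every pure
tissue plus all mixture replicates at the 10 %, 33.3 % and 50 % levels; the
prediction set holds the remaining pure replicate and the 25 % / 66.6 %
levels.  The split is made at the physical-sample level, so all acquisitions
of one sample always fall on the same side — leaking replicate acquisitions
across the split would make prediction metrics meaningless.

Classification metrics per class are sensitivity (recall), specificity
(correct classification rate among the other classes) and precision; the
overall error rate is one minus the mean per-class sensitivity, and accuracy
is total-correct over total.  Percentages in reports are rounded half-up to
integers only at display time; stored values keep full precision.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_spectra import SpectralDataset

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "ClassMetrics",
    "RegressionMetrics",
    "LeakageError",
    "make_split",
    "kfold_indices",
    "confusion_metrics",
    "error_rate_from_sensitivities",
    "accuracy_from_sensitivities",
    "display_percent",
    "regression_metrics",
    "evaluate_model",
]

CALIBRATION_FRACTIONS = (0.10, 0.333, 0.50)


class LeakageError(RuntimeError):
    """Raised when calibration-side state would be fitted on prediction rows."""


@dataclass
class SplitPlan:
    calibration_ids: list[str]
    prediction_ids: list[str]
    rule: str

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.prediction_ids)
        if overlap:
            raise LeakageError(f"samples on both sides of the split: {sorted(overlap)[:5]}")

    def calibration_mask(self, meta: pd.DataFrame) -> np.ndarray:
        return meta["sample_id"].isin(self.calibration_ids).to_numpy()

    def prediction_mask(self, meta: pd.DataFrame) -> np.ndarray:
        return meta["sample_id"].isin(self.prediction_ids).to_numpy()


def make_split(
    dataset: SpectralDataset,
    seed: int = 0,
    calibration_fractions: tuple[float, ...] = CALIBRATION_FRACTIONS,
) -> SplitPlan:
    """Sample-level calibration/prediction split following the study design.

    Pure samples: one seeded replicate per tissue type is held out for
    prediction.  Mixtures: membership is decided by the fraction level alone
    (calibration levels vs the rest), all replicates included.
    """
    meta = dataset.meta
    samples = meta.drop_duplicates("sample_id")
    cal, pred = [], []
    pure = samples[np.isin(samples["fraction"], (0.0, 1.0))]
    for cls, group in pure.groupby("class_name"):
        reps = sorted(group["replicate_id"].unique())
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(str(cls).encode())])
        )
        held_out = reps[int(rng.integers(len(reps)))] if len(reps) > 1 else None
        for _, row in group.iterrows():
            (pred if row["replicate_id"] == held_out else cal).append(row["sample_id"])
    mixtures = samples[(samples["fraction"] > 0) & (samples["fraction"] < 1)]
    cal_levels = np.asarray(calibration_fractions)
    for _, row in mixtures.iterrows():
        is_cal = np.isclose(row["fraction"], cal_levels, atol=5e-3).any()
        (cal if is_cal else pred).append(row["sample_id"])
    return SplitPlan(
        calibration_ids=sorted(cal),
        prediction_ids=sorted(pred),
        rule=(
            "calibration: all but one pure replicate per type + mixture levels "
            f"{list(calibration_fractions)}; prediction: the rest (seed={seed})"
        ),
    )


def kfold_indices(labels, k: int, seed: int = 0, groups=None) -> np.ndarray:
    """Stratified k-fold assignment; optional grouping keeps groups together.

    Returns an integer fold id per row.  Stratification is by class label;
    when ``groups`` is given (e.g. sample ids), all rows of a group land in
    one fold and stratification operates on groups.  Deterministic under
    ``seed``; classes smaller than ``k`` are spread best-effort with a
    warning.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    fold = np.full(len(labels), -1, dtype=int)
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if groups is not None:
            g = np.asarray(groups)[idx]
            units = [idx[g == u] for u in pd.unique(g)]
        else:
            units = [np.array([i]) for i in idx]
        if len(units) < k:
            warnings.warn(
                f"class {c!r} has only {len(units)} unit(s) for {k}-fold CV; spreading best-effort"
            )
        order = rng.permutation(len(units))
        for pos, ui in enumerate(order):
            fold[units[ui]] = (pos + offset) % k
        offset += len(units) % k  # stagger so small classes do not pile on fold 0
    return fold


# ---------------------------------------------------------------------------
# classification metrics


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if classes is None:
            classes = np.array(sorted(set(y_true) | set(y_pred)))
        else:
            classes = np.asarray(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, classes=classes)


@dataclass
class ClassMetrics:
    classes: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    error_rate: float
    accuracy: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
            }
        )


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class sensitivity/specificity/precision plus error rate & accuracy.

    * sensitivity_C = correct in C / total in C
    * specificity_C = correct among classes other than C / total in others
    * precision_C   = correct in C / total assigned to C
    * error rate    = 1 − mean(sensitivity)
    * accuracy      = total correct / total
    """
    counts = cm.counts.astype(float)
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        empty = cm.classes[row_tot == 0].tolist()
        raise ValueError(f"sensitivity undefined for empty classes: {empty}")
    diag = np.diag(counts)
    sens = diag / row_tot
    total = counts.sum()
    correct = diag.sum()
    spec = np.array(
        [(correct - diag[i]) / (total - row_tot[i]) if total > row_tot[i] else np.nan
         for i in range(len(cm.classes))]
    )
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col_tot > 0, diag / col_tot, np.nan)
    return ClassMetrics(
        classes=cm.classes,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        error_rate=float(1.0 - sens.mean()),
        accuracy=float(correct / total),
    )


def error_rate_from_sensitivities(sensitivities) -> float:
    """Overall error rate from per-class sensitivities: 1 − mean sensitivity."""
    return float(1.0 - np.mean(np.asarray(sensitivities, dtype=float)))


def accuracy_from_sensitivities(sensitivities, class_sizes) -> float:
    """Total-correct/total accuracy implied by per-class sensitivities."""
    s = np.asarray(sensitivities, dtype=float)
    n = np.asarray(class_sizes, dtype=float)
    return float((s * n).sum() / n.sum())


def display_percent(value: float) -> int:
    """Round a proportion to integer percent, half away from zero."""
    pct = 100.0 * value
    return int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5))


# ---------------------------------------------------------------------------
# regression metrics


@dataclass
class RegressionMetrics:
    rmse: float
    r2: float
    kind: str


def regression_metrics(y_true, y_hat, kind: str = "prediction") -> RegressionMetrics:
    """RMSE and R² under the stated convention.

    ``kind='calibration'`` uses the squared Pearson correlation of fitted vs
    true; ``'cv'`` and ``'prediction'`` use 1 − SSE/SST, which can be
    negative for a model worse than the mean.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_true.size != y_hat.size or y_true.size < 2:
        raise ValueError("y_true and y_hat must share a length >= 2")
    if np.ptp(y_true) == 0:
        raise ValueError("R^2 undefined for zero-variance y_true")
    rmse = float(np.sqrt(np.mean((y_true - y_hat) ** 2)))
    if kind == "calibration":
        if np.ptp(y_hat) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(y_true, y_hat)[0, 1] ** 2)
    elif kind in ("cv", "prediction"):
        sst = float(((y_true - y_true.mean()) ** 2).sum())
        sse = float(((y_true - y_hat) ** 2).sum())
        r2 = 1.0 - sse / sst
    else:
        raise ValueError(f"unknown metrics kind {kind!r}")
    return RegressionMetrics(rmse=rmse, r2=r2, kind=kind)


# ---------------------------------------------------------------------------
# three-block model evaluation


def evaluate_model(
    model_factory,
    X: np.ndarray,
    labels,
    cal_mask: np.ndarray,
    pred_mask: np.ndarray,
    cv_k: int = 10,
    seed: int = 0,
    groups=None,
) -> dict[str, ClassMetrics]:
    """Calibration / k-fold CV / prediction metrics for one classifier config.

    ``model_factory()`` must return an unfitted model with ``fit``/``predict``.
    Cross-validation refits the model inside each calibration fold, so any
    scaler state is re-estimated per fold — the fit-inside-fold discipline.
    Raises :class:`LeakageError` if the two masks overlap.
    """
    labels = np.asarray(labels)
    cal_mask = np.asarray(cal_mask, dtype=bool)
    pred_mask = np.asarray(pred_mask, dtype=bool)
    if (cal_mask & pred_mask).any():
        raise LeakageError("calibration and prediction masks overlap")
    if groups is not None:
        groups = np.asarray(groups)
        shared = set(groups[cal_mask]) & set(groups[pred_mask])
        if shared:
            raise LeakageError(f"groups span both sides of the split: {sorted(shared)[:5]}")
    Xc, yc = X[cal_mask], labels[cal_mask]
    classes = np.array(sorted(np.unique(labels).tolist()))

    model = model_factory().fit(Xc, yc)
    out = {
        "calibration": confusion_metrics(
            ConfusionMatrix.from_labels(yc, model.predict(Xc), classes)
        )
    }

    fold = kfold_indices(yc, cv_k, seed=seed, groups=None if groups is None else groups[cal_mask])
    cv_pred = np.empty(len(yc), dtype=object)
    for f in range(cv_k):
        test = fold == f
        if not test.any():
            continue
        m = model_factory().fit(Xc[~test], yc[~test])
        cv_pred[test] = m.predict(Xc[test])
    out["cross_validation"] = confusion_metrics(
        ConfusionMatrix.from_labels(yc, cv_pred.astype(classes.dtype), classes)
    )

    if pred_mask.any():
        out["prediction"] = confusion_metrics(
            ConfusionMatrix.from_labels(labels[pred_mask], model.predict(X[pred_mask]), classes)
        )
    return out
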