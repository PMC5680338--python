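"""Hierarchical screening protocol for unknown ground-beef samples.

The cascade never quantifies before classifying, because a pooled
all-offal regression cannot predict accurately across adulterant types:

1. **Authentication** — a 3-class canonical-variate LDA (authentic beef meat /
   with beef offal / with pork offal) on Wilks'-λ-selected variables
   (threshold 0.75, the escalated criterion used when 0.5 selects nothing at
   the 3-class level).
2. **Beef branch** — the adulterant fraction is quantified directly with the
   pooled beef-offal PLSR (9 latent variables); a SIMCA model (mean-centred,
   2/6/3 components for honey-comb tripe / liver / omasum) reports the
   subtype for information.  A merged tripe+omasum SIMCA (4 components) is
   available as an alternate.
3. **Pork branch** — a 3-class LDA (non-scaled) identifies the pork offal
   type, then the matching per-type PLSR quantifies it (heart 10, kidney 9,
   liver 6 latent variables).  A merged heart+kidney variant is available.

Multiple acquisitions of one physical sample are combined by majority vote
(ties conservatively resolved toward "adulterated"); the fraction estimate is
the median over the spectra routed to the voted branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic_spectra as syn
from .classifiers import LinearDiscriminantClassifier, SIMCAClassifier
from .feature_selection import WilksResult, select_variables, wilks_select
from .preprocessing import PreprocessSpec, apply_preprocessing
from .quantification import PLSRegressor
from .synthetic_spectra import (
    AUTHENTIC,
    BEEF_OFFAL_TYPES,
    PORK_OFFAL_TYPES,
    WITH_BEEF_OFFAL,
    WITH_PORK_OFFAL,
    SpectralDataset,
    three_class_label,
)
from .validation import ConfusionMatrix, confusion_metrics, regression_metrics

__all__ = [
    "ProtocolConfig",
    "ProtocolBundle",
    "ProtocolReport",
    "train_bundle",
    "analyze",
    "evaluate_protocol",
]

BUNDLE_VERSION = "1"

VERDICT_BY_BRANCH = {
    WITH_BEEF_OFFAL: "adulterated_beef_offal",
    WITH_PORK_OFFAL: "adulterated_pork_offal",
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Hyperparameters of every sub-model in the cascade (field defaults)."""

    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    wilks_three_class: float = 0.75
    wilks_branch: float = 0.5
    simca_beef_pcs: tuple[int, int, int] = (2, 6, 3)  # tripe, liver, omasum
    simca_merged_pcs: int = 4
    pork_lda_scaling: str = "none"
    plsr_pooled_beef_lv: int = 9
    plsr_pooled_pork_lv: int = 8
    plsr_per_type_lv: tuple[tuple[str, int], ...] = (
        ("beef honey comb tripe", 6),
        ("beef liver", 6),
        ("beef omasum", 5),
        ("pork heart", 10),
        ("pork kidney", 9),
        ("pork liver", 6),
    )
    plsr_merged_tripe_omasum_lv: int = 5
    plsr_merged_heart_kidney_lv: int = 9
    include_pure_meat_in_plsr: bool = True
    merge_beef_stomach: bool = False   # report tripe+omasum as one subtype
    merge_pork_heart_kidney: bool = False

    def per_type_lv(self) -> dict[str, int]:
        return dict(self.plsr_per_type_lv)


@dataclass
class ProtocolBundle:
    config: ProtocolConfig
    grid: syn.WavenumberGrid
    selection_three_class: WilksResult
    selection_beef: WilksResult
    selection_pork: WilksResult
    lda_three_class: LinearDiscriminantClassifier
    simca_beef: SIMCAClassifier
    simca_beef_merged: SIMCAClassifier
    lda_pork: LinearDiscriminantClassifier
    lda_pork_merged: LinearDiscriminantClassifier
    plsr_pooled_beef: PLSRegressor
    plsr_pooled_pork: PLSRegressor
    plsr_per_type: dict[str, PLSRegressor]
    plsr_merged_tripe_omasum: PLSRegressor
    plsr_merged_heart_kidney: PLSRegressor
    version: str = BUNDLE_VERSION


@dataclass
class ProtocolReport:
    verdict: str                    # authentic | adulterated_beef_offal | adulterated_pork_offal
    subtype: str                    # offal label or "not determined"
    fraction_estimate: float | None
    model_id: str | None
    trace: list[tuple[str, str, float]]  # (model, decision, score)

    def __post_init__(self) -> None:
        if (self.verdict == "authentic") != (self.fraction_estimate is None):
            raise ValueError("fraction must be present exactly when the verdict is adulterated")
        if not self.trace:
            raise ValueError("branch trace must not be empty")


def _capped_selection(sub, labels, threshold: float, max_vars: int) -> WilksResult:
    """Wilks selection, capped to the ``max_vars`` lowest-λ variables.

    On very clean data almost every variable passes the threshold, which
    would defeat the purpose of selection (LDA needs fewer variables than
    spectra); the cap keeps the most discriminative ones.
    """
    result = wilks_select(sub, labels, threshold=threshold)
    if result.n_selected > max_vars:
        lam = result.lambda_per_variable
        keep = np.sort(np.argsort(lam, kind="stable")[:max_vars])
        capped = np.full_like(lam, 1.0)
        capped[keep] = lam[keep]
        result = select_variables(capped, threshold, sub.grid)
    return result


def _merged_beef_labels(labels: np.ndarray) -> np.ndarray:
    merged = {"beef honey comb tripe": "beef stomach", "beef omasum": "beef stomach"}
    return np.array([merged.get(l, l) for l in labels], dtype=object)


def _merged_pork_labels(labels: np.ndarray) -> np.ndarray:
    merged = {"pork heart": "pork heart & kidney", "pork kidney": "pork heart & kidney"}
    return np.array([merged.get(l, l) for l in labels], dtype=object)


def train_bundle(dataset: SpectralDataset, config: ProtocolConfig = ProtocolConfig()) -> ProtocolBundle:
    """Fit every sub-model of the cascade on a calibration dataset.

    ``dataset`` is raw absorbance; preprocessing (baseline + crop) is applied
    here and its spec stored in the bundle, so unknown spectra are treated
    identically at analysis time.
    """
    present = set(dataset.meta["class_name"].unique())
    required = {syn.BEEF_MEAT, *BEEF_OFFAL_TYPES, *PORK_OFFAL_TYPES}
    missing = sorted(required - present)
    if missing:
        raise ValueError(f"calibration dataset lacks classes: {missing}")

    prep = apply_preprocessing(dataset, config.preprocess)
    X = prep.intensities
    meta = prep.meta
    y3 = three_class_label(meta)

    sel3 = _capped_selection(prep, y3, config.wilks_three_class, len(meta) // 2)
    # per-class canonical covariance: the authentic class is compact while
    # the two adulteration classes stretch along the dilution direction, so
    # a pooled metric would absorb low-fraction mixtures into the meat class
    lda3 = LinearDiscriminantClassifier(
        scaling="none", selection=sel3.selected_indices, covariance="per_class"
    )
    lda3.fit(X, y3)

    frac = meta["fraction"].to_numpy(dtype=float)
    offal = meta["offal_type"].to_numpy()

    beef_mask = (frac > 0) & np.isin(offal, BEEF_OFFAL_TYPES)
    beef_sub = prep.subset(beef_mask)
    y_beef = beef_sub.meta["offal_type"].to_numpy()
    sel_beef = _capped_selection(beef_sub, y_beef, config.wilks_branch, len(y_beef) // 2)
    pcs = dict(zip(("beef honey comb tripe", "beef liver", "beef omasum"), config.simca_beef_pcs))
    simca_beef = SIMCAClassifier(n_pcs=pcs, scaling="mean_center", selection=sel_beef.selected_indices)
    simca_beef.fit(beef_sub.intensities, y_beef)
    simca_merged = SIMCAClassifier(
        n_pcs=config.simca_merged_pcs, scaling="mean_center", selection=sel_beef.selected_indices
    )
    simca_merged.fit(beef_sub.intensities, _merged_beef_labels(y_beef))

    pork_mask = (frac > 0) & np.isin(offal, PORK_OFFAL_TYPES)
    pork_sub = prep.subset(pork_mask)
    y_pork = pork_sub.meta["offal_type"].to_numpy()
    sel_pork = _capped_selection(pork_sub, y_pork, config.wilks_branch, len(y_pork) // 2)
    lda_pork = LinearDiscriminantClassifier(
        scaling=config.pork_lda_scaling, selection=sel_pork.selected_indices
    )
    lda_pork.fit(pork_sub.intensities, y_pork)
    lda_pork_merged = LinearDiscriminantClassifier(
        scaling=config.pork_lda_scaling, selection=sel_pork.selected_indices
    )
    lda_pork_merged.fit(pork_sub.intensities, _merged_pork_labels(y_pork))

    meat_mask = frac == 0.0
    per_type_lv = config.per_type_lv()

    def quant_rows(mask: np.ndarray) -> np.ndarray:
        return mask | meat_mask if config.include_pure_meat_in_plsr else mask

    def fit_plsr(mask: np.ndarray, n_lv: int, model_id: str) -> PLSRegressor:
        rows = quant_rows(mask)
        return PLSRegressor(n_lv=n_lv, scaling="mean_center", model_id=model_id).fit(
            X[rows], frac[rows]
        )

    plsr_pooled_beef = fit_plsr(beef_mask, config.plsr_pooled_beef_lv, "plsr-pooled-beef-offal")
    plsr_pooled_pork = fit_plsr(pork_mask, config.plsr_pooled_pork_lv, "plsr-pooled-pork-offal")
    plsr_per_type = {
        t: fit_plsr((frac > 0) & (offal == t), per_type_lv[t], f"plsr-{t.replace(' ', '-')}")
        for t in BEEF_OFFAL_TYPES + PORK_OFFAL_TYPES
    }
    plsr_merged_to = fit_plsr(
        (frac > 0) & np.isin(offal, ("beef honey comb tripe", "beef omasum")),
        config.plsr_merged_tripe_omasum_lv,
        "plsr-beef-stomach",
    )
    plsr_merged_hk = fit_plsr(
        (frac > 0) & np.isin(offal, ("pork heart", "pork kidney")),
        config.plsr_merged_heart_kidney_lv,
        "plsr-pork-heart-kidney",
    )

    return ProtocolBundle(
        config=config,
        grid=dataset.grid,
        selection_three_class=sel3,
        selection_beef=sel_beef,
        selection_pork=sel_pork,
        lda_three_class=lda3,
        simca_beef=simca_beef,
        simca_beef_merged=simca_merged,
        lda_pork=lda_pork,
        lda_pork_merged=lda_pork_merged,
        plsr_pooled_beef=plsr_pooled_beef,
        plsr_pooled_pork=plsr_pooled_pork,
        plsr_per_type=plsr_per_type,
        plsr_merged_tripe_omasum=plsr_merged_to,
        plsr_merged_heart_kidney=plsr_merged_hk,
    )


def _preprocess_unknown(bundle: ProtocolBundle, spectra: SpectralDataset) -> np.ndarray:
    if spectra.grid.n_points != bundle.grid.n_points or not np.allclose(
        spectra.grid.values, bundle.grid.values
    ):
        raise ValueError("unknown spectra are not on the bundle's wavenumber grid")
    return apply_preprocessing(spectra, bundle.config.preprocess).intensities


def analyze(bundle: ProtocolBundle, spectra: SpectralDataset) -> ProtocolReport:
    """Route one unknown sample (≥1 spectra) through the cascade.

    Per-spectrum decisions are aggregated: majority vote on the branch (tie →
    adulterated, protecting the authentic-beef claim), subtype majority among
    the voted branch's spectra, fraction as the median per-spectrum estimate.
    """
    if spectra.n_spectra < 1:
        raise ValueError("analyze needs at least one spectrum")
    X = _preprocess_unknown(bundle, spectra)
    trace: list[tuple[str, str, float]] = []

    branch_pred = bundle.lda_three_class.predict(X)
    d3 = bundle.lda_three_class.distances(X)
    for i in range(len(X)):
        trace.append(("lda-3class", str(branch_pred[i]), float(d3[i].min())))

    votes = pd.Series(branch_pred).value_counts()
    n_auth = int(votes.get(AUTHENTIC, 0))
    n_adult = len(X) - n_auth
    if n_auth > n_adult:
        trace.append(("vote", "authentic", float(n_auth) / len(X)))
        return ProtocolReport("authentic", "not determined", None, None, trace)

    adult_votes = votes.drop(AUTHENTIC, errors="ignore")
    branch = adult_votes.sort_values(ascending=False).index[0] if len(adult_votes) else WITH_BEEF_OFFAL
    on_branch = branch_pred == branch
    if not on_branch.any():  # every spectrum said authentic but the tie rule fired
        on_branch = np.ones(len(X), dtype=bool)
    Xb = X[on_branch]
    trace.append(("vote", VERDICT_BY_BRANCH[branch], float(on_branch.sum()) / len(X)))

    cfg = bundle.config
    if branch == WITH_BEEF_OFFAL:
        subtype_model = bundle.simca_beef_merged if cfg.merge_beef_stomach else bundle.simca_beef
        sub_pred = subtype_model.predict(Xb)
        dists = subtype_model.class_distances(Xb)
        for i in range(len(Xb)):
            trace.append(("simca-beef", str(sub_pred[i]), float(dists[i].min())))
        subtype = pd.Series(sub_pred).value_counts().sort_values(ascending=False).index[0]
        quant = bundle.plsr_pooled_beef  # pooled quantifier on the beef branch
    else:
        subtype_model = bundle.lda_pork_merged if cfg.merge_pork_heart_kidney else bundle.lda_pork
        sub_pred = subtype_model.predict(Xb)
        dists = subtype_model.distances(Xb)
        for i in range(len(Xb)):
            trace.append(("lda-pork", str(sub_pred[i]), float(dists[i].min())))
        subtype = pd.Series(sub_pred).value_counts().sort_values(ascending=False).index[0]
        if cfg.merge_pork_heart_kidney and subtype == "pork heart & kidney":
            quant = bundle.plsr_merged_heart_kidney
        else:
            quant = bundle.plsr_per_type[str(subtype)]

    pred = quant.predict(Xb)
    fraction = float(np.median(pred.clamped_fraction))
    trace.append((quant.model_id, "fraction", fraction))
    return ProtocolReport(VERDICT_BY_BRANCH[branch], str(subtype), fraction, quant.model_id, trace)


def evaluate_protocol(bundle: ProtocolBundle, dataset: SpectralDataset) -> dict:
    """End-to-end cascade metrics on a labelled prediction dataset.

    Reports the sample-level authentication confusion, the subtype confusion
    conditional on the correct branch, and fraction recovery (RMSE / R²)
    conditional on the correct branch, per branch.
    """
    records = []
    for sample_id, idx in dataset.meta.groupby("sample_id").groups.items():
        sub = dataset.subset(np.asarray(idx))
        report = analyze(bundle, sub)
        row = sub.meta.iloc[0]
        truth3 = three_class_label(sub.meta)[0]
        records.append(
            dict(
                sample_id=sample_id,
                true_branch=truth3,
                true_subtype=row["offal_type"] or "none",
                true_fraction=float(row["fraction"]),
                verdict=report.verdict,
                pred_branch={v: k for k, v in VERDICT_BY_BRANCH.items()}.get(
                    report.verdict, AUTHENTIC
                ),
                subtype=report.subtype,
                fraction=np.nan if report.fraction_estimate is None else report.fraction_estimate,
            )
        )
    table = pd.DataFrame.from_records(records)
    auth_cm = ConfusionMatrix.from_labels(table["true_branch"], table["pred_branch"])
    out = {
        "samples": table,
        "authentication": confusion_metrics(auth_cm),
        "authentication_accuracy": float((table["true_branch"] == table["pred_branch"]).mean()),
    }
    for branch, types in ((WITH_BEEF_OFFAL, BEEF_OFFAL_TYPES), (WITH_PORK_OFFAL, PORK_OFFAL_TYPES)):
        key = "beef" if branch == WITH_BEEF_OFFAL else "pork"
        correct = table[(table["true_branch"] == branch) & (table["pred_branch"] == branch)]
        if len(correct) == 0:
            continue
        truth_sub = correct["true_subtype"].to_numpy(dtype=object)
        pred_sub = correct["subtype"].to_numpy(dtype=object)
        if key == "beef" and bundle.config.merge_beef_stomach:
            truth_sub = _merged_beef_labels(truth_sub)
        if key == "pork" and bundle.config.merge_pork_heart_kidney:
            truth_sub = _merged_pork_labels(truth_sub)
        out[f"{key}_subtype_accuracy"] = float((truth_sub == pred_sub).mean())
        if len(correct) >= 2 and correct["true_fraction"].nunique() > 1:
            reg = regression_metrics(correct["true_fraction"], correct["fraction"], "prediction")
            out[f"{key}_fraction_rmse"] = reg.rmse
            out[f"{key}_fraction_r2"] = reg.r2
    return out
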