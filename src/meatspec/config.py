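"""Run configuration, seed fan-out, and the end-to-end pipeline driver.

One user-facing integer seed fans out deterministically to per-stage seeds
(simulation, split, cross-validation) via ``stage_seed``, so a whole run is
reproducible from a single knob.  Every artifact written by ``run_pipeline``
is stamped with the configuration hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import spectra_io
from .preprocessing import PreprocessSpec
from .protocol import ProtocolConfig, evaluate_protocol, train_bundle
from .synthetic_spectra import (
    AcquisitionConfig,
    AdulterationDesign,
    generate_study_dataset,
    three_class_label,
)
from .validation import display_percent, evaluate_model, make_split

__all__ = ["RunConfig", "stage_seed", "config_hash", "run_pipeline", "save_bundle", "load_bundle"]

_STAGES = ("simulate", "split", "cv", "protocol")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed < 2^31 from the single run seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    return (int(seed) * 1_000_003 + _STAGES.index(stage)) % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full simulate→train→evaluate run depends on."""

    seed: int = 0
    noise_sd: float = 0.003
    baseline_amp: float = 0.05
    scatter_sd: float = 0.005
    biological_cv: float = 0.01
    mixture_replicates: int = 3
    pure_replicates: int = 5
    spectra_per_sample: int = 5
    fractions: tuple[float, ...] = (0.10, 0.25, 0.333, 0.50, 0.666)
    cv_folds: int = 10
    plsr_cv_folds: int = 5  # 9 supported as the alternate convention
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)

    def design(self) -> AdulterationDesign:
        return AdulterationDesign(
            fractions=tuple(self.fractions),
            mixture_replicates=self.mixture_replicates,
            pure_replicates=self.pure_replicates,
            spectra_per_sample=self.spectra_per_sample,
        )

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            noise_sd=self.noise_sd,
            baseline_amp=self.baseline_amp,
            scatter_sd=self.scatter_sd,
            seed=stage_seed(self.seed, "simulate"),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        d["preprocess"] = self.preprocess.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessSpec.from_dict(d["preprocess"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def save_bundle(bundle, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh)


def load_bundle(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate → preprocess → split → train → evaluate → report.

    Writes ``dataset.csv``, ``bundle.pkl`` and ``report.json`` under
    ``outdir`` and returns the report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    dataset = generate_study_dataset(
        design=config.design(), acq=config.acquisition(), biological_cv=config.biological_cv
    )
    spectra_io.write_wide_csv(dataset, outdir / "dataset.csv")

    split = make_split(dataset, seed=stage_seed(config.seed, "split"))
    cal = dataset.subset(split.calibration_mask(dataset.meta))
    pred = dataset.subset(split.prediction_mask(dataset.meta))

    bundle = train_bundle(cal, ProtocolConfig(preprocess=config.preprocess))
    save_bundle(bundle, outdir / "bundle.pkl")

    protocol_metrics = evaluate_protocol(bundle, pred)

    # three-block report of the front-line authentication LDA
    from .classifiers import LinearDiscriminantClassifier  # local: avoids cycle
    from .preprocessing import apply_preprocessing

    prep_all = apply_preprocessing(dataset, config.preprocess)
    labels3 = three_class_label(prep_all.meta)
    sel = bundle.selection_three_class
    blocks = evaluate_model(
        lambda: LinearDiscriminantClassifier(scaling="none", selection=sel.selected_indices),
        prep_all.intensities,
        labels3,
        split.calibration_mask(dataset.meta),
        split.prediction_mask(dataset.meta),
        cv_k=config.cv_folds,
        seed=stage_seed(config.seed, "cv"),
        groups=dataset.meta["sample_id"].to_numpy(),
    )

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_spectra": int(dataset.n_spectra),
        "n_calibration_samples": len(split.calibration_ids),
        "n_prediction_samples": len(split.prediction_ids),
        "wilks_selected_three_class": int(sel.n_selected),
        "authentication_lda": {
            block: {
                "error_rate_pct": display_percent(m.error_rate),
                "accuracy_pct": display_percent(m.accuracy),
            }
            for block, m in blocks.items()
        },
        "protocol": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else None)
            for k, v in protocol_metrics.items()
            if k not in ("samples", "authentication")
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
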