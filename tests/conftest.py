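"""Shared fixtures: one study-sized run reused across protocol tests.

The heavyweight pieces (full study dataset, fitted bundle, cascade metrics)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from meatspec.preprocessing import PreprocessSpec, apply_preprocessing
from meatspec.protocol import evaluate_protocol, train_bundle
from meatspec.synthetic_spectra import (
    AcquisitionConfig,
    generate_study_dataset,
)
from meatspec.validation import make_split

STUDY_SEED = 0  # fixed seed of the acceptance experiment


@pytest.fixture(scope="session")
def study():
    """Full default-design dataset at default noise with its split."""
    warnings.simplefilter("ignore")
    dataset = generate_study_dataset(seed=STUDY_SEED)
    split = make_split(dataset, seed=STUDY_SEED)
    cal = dataset.subset(split.calibration_mask(dataset.meta))
    pred = dataset.subset(split.prediction_mask(dataset.meta))
    return dict(dataset=dataset, split=split, cal=cal, pred=pred)


@pytest.fixture(scope="session")
def bundle(study):
    return train_bundle(study["cal"])


@pytest.fixture(scope="session")
def protocol_metrics(bundle, study):
    return evaluate_protocol(bundle, study["pred"])


@pytest.fixture(scope="session")
def noiseless_run():
    """Same experiment with every stochastic term switched off."""
    warnings.simplefilter("ignore")
    acq = AcquisitionConfig(seed=1).noiseless()
    dataset = generate_study_dataset(acq=acq, biological_cv=0.0)
    split = make_split(dataset, seed=STUDY_SEED)
    cal = dataset.subset(split.calibration_mask(dataset.meta))
    pred = dataset.subset(split.prediction_mask(dataset.meta))
    b = train_bundle(cal)
    return evaluate_protocol(b, pred)


@pytest.fixture(scope="session")
def preprocessed_study(study):
    """Baseline-corrected, cropped version of the full dataset."""
    return apply_preprocessing(study["dataset"], PreprocessSpec())
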