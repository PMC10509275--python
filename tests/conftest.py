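"""Shared fixtures: the default synthetic cohort and its LOSO evaluations.

The cohort (10 participants, seed 1) and the cross-validated reports are
expensive, so they are built once per session and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import scratchring as sr
from scratchring.models import reduced_config


@pytest.fixture(scope="session")
def cohort_spec() -> sr.CohortSpec:
    return sr.CohortSpec(n_participants=10, seed=1)


@pytest.fixture(scope="session")
def intensity_dataset(cohort_spec) -> sr.FeatureDataset:
    return sr.build_intensity_dataset(cohort_spec)


@pytest.fixture(scope="session")
def detection_dataset(cohort_spec) -> sr.FeatureDataset:
    return sr.build_detection_dataset(cohort_spec)


@pytest.fixture(scope="session")
def intensity_loso(intensity_dataset):
    """LOSO reports for the intensity task, per feature modality."""
    cfg = reduced_config("intensity")
    return {
        mod: sr.evaluate_loso(intensity_dataset, config=cfg, modality=mod, seed=1)
        for mod in ("both", "mic", "acc")
    }


@pytest.fixture(scope="session")
def detection_loso(detection_dataset):
    """LOSO reports for the detection task, per feature modality."""
    cfg = reduced_config("detection")
    return {
        mod: sr.evaluate_loso(detection_dataset, config=cfg, modality=mod, seed=1)
        for mod in ("both", "mic", "acc")
    }
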