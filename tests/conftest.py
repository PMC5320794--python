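"""Shared fixtures: models and synthetic data are built once per session."""
import numpy as np
import pytest

from lpmominer.calibration import calibrate
from lpmominer.fixtures import (FixtureSpec, load_cbm1_alignment,
                                load_training_alignment, make_decoys,
                                make_lpmo_fixture)
from lpmominer.hmm import BuildConfig, annotate_model, build_hmm
from lpmominer.mining import FamilyModelSet, build_family_models

MINING_Z = 56  # proteome size of the default fixture (5+1 positives + 50 decoys)


@pytest.fixture(scope="session")
def training():
    aln, family_map = load_training_alignment()
    return aln, family_map


@pytest.fixture(scope="session")
def combined_model(training):
    aln, _ = training
    model = build_hmm(aln)
    model.annotations = annotate_model(model, aln)
    return model


@pytest.fixture(scope="session")
def positives(combined_model):
    spec = FixtureSpec(seed=3, n_positives=5, low_complexity=True)
    return make_lpmo_fixture(spec, combined_model)


@pytest.fixture(scope="session")
def decoys(combined_model):
    return make_decoys(combined_model.null, seed=4, n=50)


@pytest.fixture(scope="session")
def calibrated_model(combined_model, positives):
    clean = [p for p in positives if p.id != "POSBIAS1"]
    return calibrate(combined_model, positives=clean, Z=MINING_Z, seed=9)


@pytest.fixture(scope="session")
def family_models(training):
    aln, family_map = training
    return build_family_models(aln, family_map, calibration_seed=1)


@pytest.fixture(scope="session")
def cbm1_model():
    aln = load_cbm1_alignment()
    model = build_hmm(aln, BuildConfig())
    model.annotations.brace1_col = None
    calibrate(model, seed=13)
    return model


@pytest.fixture(scope="session")
def model_set(calibrated_model, family_models, cbm1_model):
    return FamilyModelSet(combined=calibrated_model,
                          per_family=family_models, cbm1=cbm1_model)


@pytest.fixture(scope="session")
def proteome(positives, decoys):
    return positives + decoys
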