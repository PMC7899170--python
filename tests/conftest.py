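"""Shared fixtures: synthetic recording sets and fitted models.

Heavy artifacts (rendered datasets, segmentations, fitted models) are
session-scoped so the full pipeline runs once and is reused by unit,
property and acceptance tests alike.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from endocal import horizontal, synth, wd
from endocal.camera import default_camera, default_projector
from endocal.pipeline import measure_set4, prepare_set2, segment_set1

SEED = 7


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def projector():
    return default_projector()


@pytest.fixture(scope="session")
def set1_records(camera):
    return synth.generate_dataset(1, camera=camera, seed=SEED)


@pytest.fixture(scope="session")
def set2_records(camera, projector):
    return synth.generate_dataset(2, camera=camera, projector=projector, seed=SEED + 1)


@pytest.fixture(scope="session")
def set3_records(camera):
    return synth.generate_dataset(3, camera=camera, seed=SEED + 2)


@pytest.fixture(scope="session")
def set4_records(camera, projector):
    return synth.generate_dataset(4, camera=camera, projector=projector, seed=SEED + 3)


@pytest.fixture(scope="session")
def set1_samples(set1_records):
    return segment_set1(set1_records)


@pytest.fixture(scope="session")
def model_selection(set1_samples):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        M, N, table = horizontal.select_model(set1_samples, seed=SEED)
    return M, N, table


@pytest.fixture(scope="session")
def nonuniform_model(set1_samples, model_selection):
    M, N, _ = model_selection
    return horizontal.fit_nonuniform(set1_samples, M, N)


@pytest.fixture(scope="session")
def uniform_model(set1_samples):
    return horizontal.fit_uniform(set1_samples)


@pytest.fixture(scope="session")
def set2_matrix(set2_records):
    X, w, fovs, dotsets = prepare_set2(set2_records)
    return X, w, fovs, dotsets


@pytest.fixture(scope="session")
def wd_pca(set2_matrix):
    X, w, _, _ = set2_matrix
    return wd.WorkingDistanceEstimator(method="pca").fit(X, w)


@pytest.fixture(scope="session")
def set4_measurements(set4_records, wd_pca, nonuniform_model, uniform_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return measure_set4(
            set4_records, wd_pca, nonuniform_model, uniform=uniform_model
        )


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
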