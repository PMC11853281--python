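"""Shared fixtures.

The expensive fixtures (the multi-subject synthetic study and its
leave-one-out report) are session-scoped and lazy: only tests that request
them pay for them, and they are computed once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from neomotion.classifier import ForestConfig, fit_forest
from neomotion.denoise import DepthDiffFrame
from neomotion.depth_io import DepthFrame
from neomotion.evaluation import loocv
from neomotion.pipeline import build_dataset
from neomotion.synthetic import SceneConfig, generate_study

# conditions of the end-to-end detection experiment: a reduced synthetic
# study (8 subjects x 3 clips x 120 s at the default scene geometry)
STUDY_N_SUBJECTS = 8
STUDY_CLIPS_PER_SUBJECT = 3
STUDY_DURATION_S = 120.0
STUDY_SEED = 20240
LOOCV_SEED = 7


def make_frame(depths, valid_range=(200.0, 1000.0), timestamp=0.0) -> DepthFrame:
    return DepthFrame(
        np.asarray(depths, dtype=float), timestamp=timestamp, valid_range=valid_range
    )


def make_diff(diffs, mask=None, second_index=0) -> DepthDiffFrame:
    diffs = np.asarray(diffs, dtype=float)
    if mask is None:
        mask = np.ones_like(diffs, dtype=bool)
    return DepthDiffFrame(diffs, np.asarray(mask, dtype=bool), second_index=second_index)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_clips():
    """Per-second labelled features of the reduced synthetic study."""
    scene = SceneConfig(duration_s=STUDY_DURATION_S)
    plan = generate_study(
        STUDY_N_SUBJECTS, STUDY_CLIPS_PER_SUBJECT, seed=STUDY_SEED, scene=scene
    )
    return build_dataset(plan)


@pytest.fixture(scope="session")
def study_report(study_clips):
    """Leave-one-out report over the reduced synthetic study."""
    return loocv(study_clips, ForestConfig(), seed=LOOCV_SEED)


@pytest.fixture(scope="session")
def study_model(study_clips):
    """A forest trained on the whole reduced study (for transfer tests)."""
    import pandas as pd

    X = pd.concat([c.features for c in study_clips], ignore_index=True)
    y = np.concatenate([c.labels.labels for c in study_clips])
    return fit_forest(X, y, ForestConfig(seed=99))
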