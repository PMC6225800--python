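"""Shared fixtures: small rendered cohorts and trained landmark models.

Everything is generated programmatically at session start; the heavier
CLM fixture (rendered images + trained detector/regressors/shape model)
is shared between the unit tests and the acceptance suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from kneestudy.cohort import CohortConfig, generate_cohort, generate_cohort_table
from kneestudy.search import (
    DetectorModel,
    PatchConfig,
    PatchRegressorSet,
    bounding_box,
    train_detector,
    train_point_regressors,
)
from kneestudy.shape import ShapeModel, build_shape_model, procrustes_align


@pytest.fixture(scope="session")
def small_cohort_table():
    """Tabular cohort (no images), n=600, generator defaults."""
    return generate_cohort_table(CohortConfig(n_subjects=600, seed=42))


@pytest.fixture(scope="session")
def rendered_cohort():
    """Small rendered PA cohort for shape/appearance unit tests."""
    knees, manifest = generate_cohort(
        CohortConfig(n_subjects=25, seed=7, image_size=160), render=True
    )
    return knees, manifest


@dataclass
class ClmSetup:
    train_knees: list
    test_knees: list
    shape_model: ShapeModel
    regressors: PatchRegressorSet
    detector: DetectorModel
    image_size: int


@pytest.fixture(scope="session")
def clm_setup():
    """Trained CLM stack: 40 training images, 50 held-out, PA view.

    Session-scoped because regressor training dominates the suite's cost.
    """
    image_size = 192
    knees, _ = generate_cohort(
        CohortConfig(n_subjects=90, seed=11, image_size=image_size), render=True
    )
    train, test = knees[:40], knees[40:]
    aligned, _, _ = procrustes_align([k.true_landmarks for k in train])
    shape_model = build_shape_model(aligned, variance_retained=0.98)
    regressors = train_point_regressors(
        [k.image for k in train],
        [k.true_landmarks for k in train],
        PatchConfig(seed=0),
    )
    detector = train_detector(
        [k.image for k in train],
        [bounding_box(k.true_landmarks) for k in train],
        seed=0,
    )
    return ClmSetup(
        train_knees=train,
        test_knees=test,
        shape_model=shape_model,
        regressors=regressors,
        detector=detector,
        image_size=image_size,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
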