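#!/usr/bin/env python
"""Train the landmark and appearance models on the rendered cohort.

Uses the first 200 knees of the rendered cohort as the training split:
generalized Procrustes + shape PCA, the combined appearance model, the
bounding-box detector and the per-landmark patch regressors.  Models are
serialized to scratch/models/; a summary of retained modes goes to
results/.
"""

import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from kneestudy.appearance import train_appearance_model
from kneestudy.landmarks import read_points
from kneestudy.search import (
    PatchConfig,
    bounding_box,
    train_detector,
    train_point_regressors,
)
from kneestudy.shape import build_shape_model, procrustes_align

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort_pa"
MODELS = ROOT / "scratch" / "models"
RESULTS = ROOT / "results"

N_TRAIN = 200


def main() -> None:
    MODELS.mkdir(parents=True, exist_ok=True)
    ids = [p.stem for p in sorted((SCRATCH / "points").glob("*.pts"))][:N_TRAIN]
    images = [
        np.asarray(iio.imread(SCRATCH / "images" / f"{k}.png"), float) / 255.0
        for k in ids
    ]
    lms = [read_points(SCRATCH / "points" / f"{k}.pts") for k in ids]

    t0 = time.time()
    aligned, _, _ = procrustes_align(lms)
    shape_model = build_shape_model(aligned, variance_retained=0.98)
    shape_model.save(MODELS / "pa_shape.shm.npz")

    appearance = train_appearance_model(images, lms, variance_retained=0.95)
    appearance.save(MODELS / "pa_appearance.apm.npz")

    detector = train_detector(images, [bounding_box(l) for l in lms], seed=0)
    detector.save(MODELS / "pa_detector.joblib")

    regressors = train_point_regressors(images, lms, PatchConfig(seed=0))
    regressors.save(MODELS / "pa_regressors.joblib")
    elapsed = time.time() - t0

    summary = pd.DataFrame(
        [
            {
                "n_train": len(ids),
                "shape_modes": shape_model.n_modes,
                "texture_modes": appearance.texture_model.n_modes,
                "combined_params": appearance.n_params,
                "shape_weight_ws": appearance.shape_weight,
                "train_seconds": round(elapsed, 1),
            }
        ]
    )
    summary.to_csv(RESULTS / "model_summary.csv", index=False, float_format="%.4f")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
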