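#!/usr/bin/env python
"""Automatic landmark search on the held-out rendered knees.

Runs detector initialisation + CLM refinement on the 60 knees not used
for training and reports point-to-point errors against the generator's
ground truth.
"""

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from kneestudy.landmarks import read_points
from kneestudy.search import DetectorModel, PatchRegressorSet, clm_fit
from kneestudy.shape import ShapeModel

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort_pa"
MODELS = ROOT / "scratch" / "models"
RESULTS = ROOT / "results"

N_TRAIN = 200


def main() -> None:
    shape_model = ShapeModel.load(MODELS / "pa_shape.shm.npz")
    detector = DetectorModel.load(MODELS / "pa_detector.joblib")
    regressors = PatchRegressorSet.load(MODELS / "pa_regressors.joblib")

    ids = [p.stem for p in sorted((SCRATCH / "points").glob("*.pts"))][N_TRAIN:]
    out_pts = SCRATCH / "fitted_points"
    out_pts.mkdir(exist_ok=True)
    rows = []
    for k in ids:
        img = np.asarray(iio.imread(SCRATCH / "images" / f"{k}.png"), float) / 255.0
        truth = read_points(SCRATCH / "points" / f"{k}.pts")
        fit = clm_fit(
            img, shape_model, regressors, detector=detector, truth=truth
        )
        from kneestudy.landmarks import write_points

        write_points(out_pts / f"{k}.pts", fit.landmarks)
        rows.append(
            {
                "id": k,
                "iterations": fit.iterations,
                "converged": fit.converged,
                "mean_error_px": fit.mean_point_error_vs_truth,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "landmark_errors.csv", index=False, float_format="%.4f")
    err = table["mean_error_px"]
    print(
        f"fitted {len(table)} held-out knees: "
        f"median error {err.median():.2f} px, 90th pct {err.quantile(0.9):.2f} px, "
        f"{table['converged'].mean():.0%} converged"
    )


if __name__ == "__main__":
    main()
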