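"""Automatic landmark localisation: detection + constrained local model.

A coarse random-forest regressor first predicts a bounding box around the
joint from downsampled intensity and gradient features.  The mean shape is
initialised inside the box and refined by regression voting: per-landmark
random-forest patch regressors predict the displacement from a sampled
patch centre to the true landmark position; votes from a grid of patches
accumulate into a response map, each map's peak proposes a candidate, and
a similarity pose plus shape parameters are least-squares fitted to the
candidates with the parameters clamped to the point-distribution model's
plausibility box (``|b_j| <= k sqrt(lambda_j)``, k = 3).  The loop repeats
until the landmarks stop moving.

Single-resolution search throughout: the synthetic images are clean enough
that no coarse-to-fine pyramid is needed (a deliberate divergence from
production CLM systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from skimage.filters import sobel
from skimage.transform import resize
from sklearn.ensemble import RandomForestRegressor

from .landmarks import LandmarkSet, view_n_points
from .shape import (
    ShapeModel,
    constrain_params,
    params_to_shape,
    shape_to_params,
)

# ---------------------------------------------------------------------------
# patch utilities


def _pad_image(image: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(np.asarray(image, dtype=float), pad, mode="edge")


def _extract_patches(
    padded: np.ndarray, pad: int, centres: np.ndarray, patch_size: int
) -> np.ndarray:
    """Normalised flattened patches at integer centres (x, y)."""
    half = patch_size // 2
    out = np.empty((len(centres), patch_size * patch_size))
    for i, (cx, cy) in enumerate(centres):
        r0 = int(cy) + pad - half
        c0 = int(cx) + pad - half
        out[i] = padded[r0 : r0 + patch_size, c0 : c0 + patch_size].ravel()
    mu = out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd < 1e-9] = 1.0
    return (out - mu) / sd


# ---------------------------------------------------------------------------
# global joint detector


@dataclass
class DetectorModel:
    """Coarse whole-image regressor for the joint bounding box."""

    model: RandomForestRegressor
    grid: int = 16

    def features(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        small = resize(img, (self.grid, self.grid), anti_aliasing=True)
        grad = resize(sobel(img), (self.grid, self.grid), anti_aliasing=True)
        return np.concatenate([small.ravel(), grad.ravel()])

    def predict_box(self, image: np.ndarray) -> tuple[float, float, float]:
        """Predicted (centre_x, centre_y, width); always returns one box."""
        cx, cy, logw = self.model.predict(self.features(image)[None, :])[0]
        return float(cx), float(cy), float(np.exp(logw))

    def save(self, path: str | Path) -> None:
        joblib.dump({"kind": "kneestudy-detector", "grid": self.grid, "model": self.model}, path)

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        d = joblib.load(path)
        if d.get("kind") != "kneestudy-detector":
            raise ValueError(f"{path} is not a detector file")
        return cls(model=d["model"], grid=d["grid"])


def bounding_box(lms: LandmarkSet, margin: float = 0.10) -> tuple[float, float, float]:
    """(centre_x, centre_y, width) of the landmark bounding box with margin."""
    lo = lms.points.min(axis=0)
    hi = lms.points.max(axis=0)
    centre = (lo + hi) / 2.0
    width = float((hi - lo).max() * (1 + 2 * margin))
    return float(centre[0]), float(centre[1]), width


def train_detector(
    images: list[np.ndarray],
    boxes: list[tuple[float, float, float]],
    n_trees: int = 25,
    seed: int = 0,
) -> DetectorModel:
    """Fit the bounding-box regressor on (image, true box) pairs."""
    if len(images) < 10:
        raise ValueError(f"need at least 10 examples to train a detector, got {len(images)}")
    det = DetectorModel(
        model=RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1, min_samples_leaf=2
        )
    )
    x = np.stack([det.features(img) for img in images])
    y = np.array([[cx, cy, np.log(w)] for cx, cy, w in boxes])
    det.model.fit(x, y)
    return det


# ---------------------------------------------------------------------------
# per-landmark patch regressors


@dataclass(frozen=True)
class PatchConfig:
    patch_size: int = 15          # odd, pixels
    sampling_range: int = 16      # max |offset| of training patches, pixels
    trees_per_regressor: int = 10
    samples_per_image: int = 20
    min_samples_leaf: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd, got {self.patch_size}")


@dataclass
class PatchRegressorSet:
    """One displacement regressor per landmark of a view."""

    view: str
    config: PatchConfig
    regressors: list[RandomForestRegressor] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "kind": "kneestudy-regressors",
                "view": self.view,
                "config": self.config,
                "regressors": self.regressors,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchRegressorSet":
        d = joblib.load(path)
        if d.get("kind") != "kneestudy-regressors":
            raise ValueError(f"{path} is not a regressor-set file")
        return cls(view=d["view"], config=d["config"], regressors=d["regressors"])


def train_point_regressors(
    images: list[np.ndarray],
    landmark_sets: list[LandmarkSet],
    config: PatchConfig = PatchConfig(),
) -> PatchRegressorSet:
    """Train patch -> displacement regressors for every landmark.

    Patches are sampled at integer offsets uniform in
    ``[-sampling_range, sampling_range]^2`` around the true position; the
    regression target is the (dx, dy) from the patch centre back to the
    true landmark.
    """
    view = landmark_sets[0].view
    n_points = view_n_points(view)
    rng = np.random.default_rng(config.seed)
    pad = config.patch_size // 2 + config.sampling_range + 2
    padded = [_pad_image(img, pad) for img in images]
    truths = [l.points for l in landmark_sets]

    # pre-draw offsets: (image, landmark, sample, 2)
    offsets = rng.integers(
        -config.sampling_range,
        config.sampling_range + 1,
        size=(len(images), n_points, config.samples_per_image, 2),
    )
    regs: list[RandomForestRegressor] = []
    for l in range(n_points):
        feats = []
        targets = []
        for i, p in enumerate(padded):
            true = truths[i][l]
            centres = np.round(true) + offsets[i, l]
            feats.append(_extract_patches(p, pad, centres, config.patch_size))
            targets.append(true - centres)
        rf = RandomForestRegressor(
            n_estimators=config.trees_per_regressor,
            random_state=config.seed + 31 * l + 1,
            min_samples_leaf=config.min_samples_leaf,
            n_jobs=1,
        )
        rf.fit(np.vstack(feats), np.vstack(targets))
        regs.append(rf)
    return PatchRegressorSet(view=view, config=config, regressors=regs)


# ---------------------------------------------------------------------------
# response maps and CLM fitting


@dataclass
class ResponseMap:
    """Accumulated displacement votes for one landmark."""

    votes: np.ndarray   # (side, side) non-negative counts, [row=y, col=x]
    origin: np.ndarray  # (x, y) image coordinates of votes[0, 0]

    def peak(self) -> np.ndarray:
        """Vote-peak position in image coordinates (x, y); ties resolve to
        the smallest (row, col)."""
        r, c = np.unravel_index(int(np.argmax(self.votes)), self.votes.shape)
        return self.origin + np.array([c, r], dtype=float)


def compute_response_maps(
    image: np.ndarray,
    current: LandmarkSet,
    regressors: PatchRegressorSet,
    search_radius: int = 12,
    grid_step: int = 2,
) -> list[ResponseMap]:
    """Regression-voting response map per landmark.

    Patches on a grid within ``search_radius`` of the current estimate
    each cast one vote at (patch centre + predicted displacement); votes
    landing outside the map region are dropped.
    """
    cfg = regressors.config
    pad = cfg.patch_size // 2 + search_radius + cfg.sampling_range + 2
    padded = _pad_image(image, pad)
    half_side = search_radius + cfg.sampling_range
    side = 2 * half_side + 1
    g = np.arange(-search_radius, search_radius + 1, grid_step)
    gx, gy = np.meshgrid(g, g)
    grid = np.column_stack([gx.ravel(), gy.ravel()])  # row-major grid order
    maps: list[ResponseMap] = []
    for l, rf in enumerate(regressors.regressors):
        centre = np.round(current.points[l]).astype(int)
        centres = centre + grid
        feats = _extract_patches(padded, pad, centres, cfg.patch_size)
        pred = rf.predict(feats)
        votes_xy = centres + pred
        origin = centre - half_side
        votes = np.zeros((side, side))
        ij = np.round(votes_xy - origin).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < side) & (ij[:, 1] >= 0) & (ij[:, 1] < side)
        np.add.at(votes, (ij[ok, 1], ij[ok, 0]), 1.0)
        maps.append(ResponseMap(votes=votes, origin=origin.astype(float)))
    return maps


@dataclass
class FitResult:
    landmarks: LandmarkSet
    iterations: int
    converged: bool
    mean_point_error_vs_truth: float | None = None


def point_to_point_error(fit: LandmarkSet, truth: LandmarkSet) -> float:
    """Mean Euclidean distance between corresponding landmarks, pixels."""
    if fit.view != truth.view:
        raise ValueError("cannot compare landmark sets of different views")
    return float(np.mean(np.linalg.norm(fit.points - truth.points, axis=1)))


def init_from_box(
    shape_model: ShapeModel, box: tuple[float, float, float], fill: float = 0.80
) -> LandmarkSet:
    """Place the mean shape inside a detected box at a given fill fraction."""
    cx, cy, w = box
    mean = shape_model.mean.reshape(-1, 2)
    span = (mean.max(axis=0) - mean.min(axis=0)).max()
    scale = fill * w / span
    centre = (mean.max(axis=0) + mean.min(axis=0)) / 2.0
    pts = (mean - centre) * scale + np.array([cx, cy])
    return LandmarkSet(shape_model.view, pts)


def clm_fit(
    image: np.ndarray,
    shape_model: ShapeModel,
    regressors: PatchRegressorSet,
    detector: DetectorModel | None = None,
    init: LandmarkSet | None = None,
    max_iters: int = 20,
    tol: float = 0.5,
    search_radius: int = 12,
    grid_step: int = 2,
    k: float = 3.0,
    truth: LandmarkSet | None = None,
) -> FitResult:
    """Constrained local model search.

    Starts from ``init`` if given, otherwise from the mean shape placed in
    the detector's box.  Each iteration computes response maps, takes each
    map's peak as a candidate, least-squares fits pose + shape parameters
    to the candidates, clamps the parameters to the k=3 plausibility box
    and regenerates the landmarks; stops when the mean landmark movement
    falls below ``tol`` pixels.  Deterministic given models and image.
    """
    if regressors.view != shape_model.view:
        raise ValueError(
            f"view mismatch: regressors are {regressors.view}, "
            f"shape model is {shape_model.view}"
        )
    if init is None:
        if detector is None:
            raise ValueError("clm_fit needs either an init shape or a detector")
        init = init_from_box(shape_model, detector.predict_box(image))
    if init.view != shape_model.view:
        raise ValueError("init landmarks view does not match shape model view")

    current = init.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iters + 1):
        maps = compute_response_maps(
            image, current, regressors, search_radius, grid_step
        )
        candidates = LandmarkSet(
            shape_model.view, np.stack([m.peak() for m in maps])
        )
        b, pose = shape_to_params(candidates, shape_model)
        b = constrain_params(b, shape_model, k)
        new = params_to_shape(b, pose, shape_model)
        movement = float(
            np.mean(np.linalg.norm(new.points - current.points, axis=1))
        )
        current = new
        if movement < tol:
            converged = True
            break
    err = point_to_point_error(current, truth) if truth is not None else None
    return FitResult(
        landmarks=current,
        iterations=iterations,
        converged=converged,
        mean_point_error_vs_truth=err,
    )
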