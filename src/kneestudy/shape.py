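"""Point-distribution shape modelling.

Generalized Procrustes alignment (similarity transforms only, no tangent
projection), PCA of the aligned configurations, and the parameterisation
used by the constrained local model search: a shape is ``pose(mean + P b)``
with pose a similarity transform, P the orthonormal mode matrix and b the
shape parameter vector, clamped to ``|b_j| <= k sqrt(lambda_j)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landmarks import LandmarkSet


@dataclass
class SimilarityTransform:
    """x -> scale * R(rotation) @ x + translation, image convention."""

    scale: float
    rotation: float
    translation: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        m = inv_scale * np.array([[c, -s], [s, c]])
        return SimilarityTransform(inv_scale, inv_rot, -(m @ self.translation))


def _as_complex(pts: np.ndarray) -> np.ndarray:
    return pts[:, 0] + 1j * pts[:, 1]


def align_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Closed form via complex regression on centred coordinates; rotations
    only (no reflection), which is the convention for radiographs of a
    fixed laterality.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    zs = _as_complex(src - mu_s)
    zd = _as_complex(dst - mu_d)
    denom = np.vdot(zs, zs).real
    if denom < 1e-12:
        raise ValueError("degenerate shape: all points coincident")
    a = np.vdot(zs, zd) / denom  # conj(zs) . zd / |zs|^2
    scale = abs(a)
    if scale < 1e-12:
        raise ValueError("degenerate alignment: zero scale")
    rot = np.angle(a)
    t = SimilarityTransform(scale, rot, np.zeros(2))
    return SimilarityTransform(scale, rot, mu_d - t.matrix @ mu_s)


def _normalize(pts: np.ndarray) -> np.ndarray:
    """Centroid at origin, unit RMS point norm."""
    c = pts - pts.mean(axis=0)
    rms = np.sqrt((c**2).sum() / len(c))
    if rms < 1e-12:
        raise ValueError("degenerate shape: all points coincident")
    return c / rms


def procrustes_align(
    shapes: list[LandmarkSet],
    tol: float = 1e-8,
    max_iters: int = 100,
) -> tuple[list[LandmarkSet], LandmarkSet, list[SimilarityTransform]]:
    """Generalized Procrustes alignment of same-topology shapes.

    Iteratively aligns every shape to the current mean by similarity
    transform, re-estimates and re-normalises the mean (centroid at the
    origin, unit RMS scale) until the mean moves by less than ``tol`` RMS.
    Returns the aligned shapes, the final mean and the image-frame-to-
    aligned-frame transforms.
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes to align")
    view = shapes[0].view
    if any(s.view != view for s in shapes):
        raise ValueError("mixed views/topologies passed to procrustes_align")
    raw = [s.points for s in shapes]
    mean = _normalize(raw[0])
    aligned = list(raw)
    for _ in range(max_iters):
        transforms = [align_similarity(p, mean) for p in raw]
        aligned = [t.apply(p) for t, p in zip(transforms, raw)]
        new_mean = _normalize(np.mean(aligned, axis=0))
        delta = np.sqrt(((new_mean - mean) ** 2).sum() / len(mean))
        mean = new_mean
        if delta < tol:
            break
    transforms = [align_similarity(p, mean) for p in raw]
    aligned_sets = [
        LandmarkSet(view, t.apply(p)) for t, p in zip(transforms, raw)
    ]
    return aligned_sets, LandmarkSet(view, mean), transforms


@dataclass
class ShapeModel:
    """PCA point-distribution model in the Procrustes-aligned frame."""

    view: str
    mean: np.ndarray          # (2N,) flattened mean shape
    modes: np.ndarray         # (2N, t) orthonormal columns
    eigenvalues: np.ndarray   # (t,) non-increasing, positive
    variance_retained: float
    total_variance: float     # trace of the aligned-data covariance

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def mean_shape(self) -> LandmarkSet:
        return LandmarkSet.from_vector(self.view, self.mean)

    def save(self, path: str | Path) -> None:
        meta = {
            "format": "kneestudy-shape-model",
            "version": 1,
            "view": self.view,
            "variance_retained": self.variance_retained,
            "total_variance": self.total_variance,
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            mean=self.mean,
            modes=self.modes,
            eigenvalues=self.eigenvalues,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            if meta.get("format") != "kneestudy-shape-model":
                raise ValueError(f"{path} is not a shape model file")
            return cls(
                view=meta["view"],
                mean=z["mean"],
                modes=z["modes"],
                eigenvalues=z["eigenvalues"],
                variance_retained=meta["variance_retained"],
                total_variance=meta["total_variance"],
            )


def _pca(vectors: np.ndarray, variance_retained: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """PCA with the retention rule shared by shape/texture/combined models.

    Returns (mean, modes, eigenvalues, total_variance); eigenvalues are the
    sample (ddof=1) variances along each retained mode.
    """
    if not 0 < variance_retained <= 1:
        raise ValueError(f"variance_retained must be in (0, 1], got {variance_retained}")
    n = vectors.shape[0]
    mean = vectors.mean(axis=0)
    x = vectors - mean
    # economy SVD: eigenvalues of cov = s^2 / (n - 1)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    lam = s**2 / (n - 1)
    total = float(lam.sum())
    # drop numerically-zero directions
    keep = lam > max(total, 1.0) * 1e-12
    lam, vt = lam[keep], vt[keep]
    if lam.size == 0:
        return mean, np.zeros((vectors.shape[1], 0)), np.zeros(0), total
    cum = np.cumsum(lam) / total
    t = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    t = min(t, lam.size)
    return mean, vt[:t].T.copy(), lam[:t].copy(), total


def build_shape_model(
    aligned: list[LandmarkSet],
    variance_retained: float = 0.95,
) -> ShapeModel:
    """PCA of Procrustes-aligned shape vectors.

    Retains the smallest number of modes whose cumulative eigenvalue
    fraction reaches ``variance_retained``.
    """
    if len(aligned) < 3:
        raise ValueError("need at least 3 shapes to build a shape model")
    view = aligned[0].view
    vectors = np.stack([s.as_vector() for s in aligned])
    mean, modes, lam, total = _pca(vectors, variance_retained)
    return ShapeModel(
        view=view,
        mean=mean,
        modes=modes,
        eigenvalues=lam,
        variance_retained=variance_retained,
        total_variance=total,
    )


def params_to_shape(
    b: np.ndarray,
    pose: SimilarityTransform,
    model: ShapeModel,
) -> LandmarkSet:
    """Instantiate ``pose(mean + P b)`` as an image-frame landmark set."""
    b = np.asarray(b, dtype=float)
    if b.shape != (model.n_modes,):
        raise ValueError(f"b must have length {model.n_modes}, got {b.shape}")
    pts = (model.mean + model.modes @ b).reshape(-1, 2)
    return LandmarkSet(model.view, pose.apply(pts))


def shape_to_params(
    shape: LandmarkSet,
    model: ShapeModel,
    max_iters: int = 100,
    tol: float = 1e-12,
) -> tuple[np.ndarray, SimilarityTransform]:
    """Project a shape onto the model: recover (b, pose).

    Alternates pose estimation (similarity Procrustes of the current model
    instance onto the shape) with linear projection of the pose-free
    residual onto the modes, to convergence.  Exact up to truncation error
    when the shape lies in the model subspace.
    """
    if shape.view != model.view:
        raise ValueError("shape view does not match model view")
    target = shape.points
    b = np.zeros(model.n_modes)
    pose = align_similarity(model.mean.reshape(-1, 2), target)
    for _ in range(max_iters):
        model_pts = (model.mean + model.modes @ b).reshape(-1, 2)
        pose = align_similarity(model_pts, target)
        y = pose.inverse().apply(target).reshape(-1)
        b_new = model.modes.T @ (y - model.mean)
        if np.max(np.abs(b_new - b), initial=0.0) < tol:
            b = b_new
            break
        b = b_new
    return b, pose


def constrain_params(b: np.ndarray, model: ShapeModel, k: float = 3.0) -> np.ndarray:
    """Clamp each parameter to the plausibility box |b_j| <= k sqrt(lambda_j)."""
    bound = k * np.sqrt(model.eigenvalues)
    return np.clip(np.asarray(b, dtype=float), -bound, bound)
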