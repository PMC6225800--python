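"""Texture sampling and the combined shape+texture appearance model.

Texture is sampled by a piecewise-affine warp from each image (under its
landmarks) into a shape-normalised reference frame: the model mean shape
scaled to a fixed width, Delaunay-triangulated once and frozen.  The
combined model stacks variance-balanced shape parameters on texture
parameters, ``[W_s b_s ; b_g]`` with
``W_s = sqrt(sum(texture eigenvalues) / sum(shape eigenvalues))``, and
takes a further PCA; the resulting parameter vector ``c`` is the
"automated" appearance feature set, with ``b_s`` and ``b_g`` exposed as
the shape-only and texture-only alternatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

from .landmarks import LandmarkSet
from .shape import ShapeModel, _pca, shape_to_params


@dataclass
class ReferenceFrame:
    """Frozen warp target: scaled mean shape, triangulation, sample pixels."""

    ref_points: np.ndarray        # (N, 2) mean shape in frame pixels
    triangles: np.ndarray         # (T, 3) vertex indices
    sample_simplex: np.ndarray    # (m,) triangle index per sampled pixel
    sample_bary: np.ndarray       # (m, 3) barycentric coords per pixel
    frame_shape: tuple[int, int]  # (height, width)
    sample_pixels: np.ndarray     # (m, 2) integer (x, y) of sampled pixels

    @property
    def n_samples(self) -> int:
        return len(self.sample_simplex)


def build_reference_frame(
    mean_shape: LandmarkSet, frame_width: int = 128, margin: int = 2
) -> ReferenceFrame:
    """Scale the mean shape to ``frame_width`` pixels, Delaunay-triangulate
    it, and precompute barycentric coordinates of every frame pixel inside
    the convex hull (row-major order)."""
    pts = mean_shape.points
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    scale = (frame_width - 1 - 2 * margin) / span[0]
    ref = (pts - lo) * scale + margin
    height = int(np.ceil(ref[:, 1].max())) + margin + 1
    width = frame_width
    tri = Delaunay(ref)
    yy, xx = np.mgrid[0:height, 0:width]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    simplex = tri.find_simplex(pix)
    inside = simplex >= 0
    pix_in = pix[inside]
    simplex_in = simplex[inside]
    # barycentric coordinates from Delaunay's affine transform per simplex
    trans = tri.transform[simplex_in]
    b2 = np.einsum("ijk,ik->ij", trans[:, :2, :2], pix_in - trans[:, 2])
    bary = np.column_stack([b2, 1.0 - b2.sum(axis=1)])
    return ReferenceFrame(
        ref_points=ref,
        triangles=tri.simplices.copy(),
        sample_simplex=simplex_in.astype(np.int32),
        sample_bary=bary,
        frame_shape=(height, width),
        sample_pixels=pix_in.astype(np.int32),
    )


def warp_to_reference(
    image: np.ndarray,
    landmarks: LandmarkSet,
    frame: ReferenceFrame,
) -> np.ndarray:
    """Sample the image texture in the reference frame (row-major vector).

    Each sampled frame pixel maps into the image through the barycentric
    coordinates of its triangle applied to the image-frame landmarks;
    intensities are read with bilinear interpolation, out-of-image samples
    clamping to the nearest valid pixel.
    """
    pts = landmarks.points
    tri_pts = pts[frame.triangles[frame.sample_simplex]]  # (m, 3, 2)
    e1 = tri_pts[:, 1] - tri_pts[:, 0]
    e2 = tri_pts[:, 2] - tri_pts[:, 0]
    areas = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]) / 2.0
    bad = np.where(areas < 1e-9)[0]
    if bad.size:
        t = int(frame.sample_simplex[bad[0]])
        raise ValueError(
            f"degenerate source triangle {t} (vertices "
            f"{frame.triangles[t].tolist()}): area < 1e-9 px^2"
        )
    src = np.einsum("mv,mvk->mk", frame.sample_bary, tri_pts)
    # map_coordinates wants (row, col) = (y, x)
    return map_coordinates(
        np.asarray(image, dtype=float),
        [src[:, 1], src[:, 0]],
        order=1,
        mode="nearest",
    )


def normalize_texture(g: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance photometric normalisation."""
    g = np.asarray(g, dtype=float)
    mu = g.mean()
    sd = g.std()
    if sd < 1e-12:
        return np.zeros_like(g)
    return (g - mu) / sd


@dataclass
class TextureModel:
    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    variance_retained: float
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def project(self, g_norm: np.ndarray) -> np.ndarray:
        return self.modes.T @ (g_norm - self.mean)

    def reconstruct(self, b_g: np.ndarray) -> np.ndarray:
        return self.mean + self.modes @ b_g


def build_texture_model(
    textures: list[np.ndarray] | np.ndarray,
    variance_retained: float = 0.95,
    normalized: bool = False,
) -> TextureModel:
    """Photometrically normalise texture vectors and PCA them (same
    retention rule as the shape model)."""
    arr = np.stack([t if normalized else normalize_texture(t) for t in textures])
    mean, modes, lam, total = _pca(arr, variance_retained)
    return TextureModel(
        mean=mean,
        modes=modes,
        eigenvalues=lam,
        variance_retained=variance_retained,
        total_variance=total,
    )


@dataclass
class CombinedModel:
    """Combined appearance model over paired (shape, texture) parameters."""

    shape_model: ShapeModel
    texture_model: TextureModel
    frame: ReferenceFrame
    shape_weight: float           # W_s
    mean: np.ndarray              # mean of [W_s b_s ; b_g] over training
    modes: np.ndarray             # ((t+s) x K) orthonormal
    eigenvalues: np.ndarray
    variance_retained: float
    total_variance: float

    @property
    def n_params(self) -> int:
        return self.modes.shape[1]

    def save(self, path: str | Path) -> None:
        meta = {
            "format": "kneestudy-appearance-model",
            "version": 1,
            "view": self.shape_model.view,
            "shape_weight": self.shape_weight,
            "variance_retained": self.variance_retained,
            "total_variance": self.total_variance,
            "shape_variance_retained": self.shape_model.variance_retained,
            "shape_total_variance": self.shape_model.total_variance,
            "texture_variance_retained": self.texture_model.variance_retained,
            "texture_total_variance": self.texture_model.total_variance,
            "frame_shape": list(self.frame.frame_shape),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            shape_mean=self.shape_model.mean,
            shape_modes=self.shape_model.modes,
            shape_eigenvalues=self.shape_model.eigenvalues,
            tex_mean=self.texture_model.mean,
            tex_modes=self.texture_model.modes,
            tex_eigenvalues=self.texture_model.eigenvalues,
            ref_points=self.frame.ref_points,
            triangles=self.frame.triangles,
            sample_simplex=self.frame.sample_simplex,
            sample_bary=self.frame.sample_bary,
            sample_pixels=self.frame.sample_pixels,
            comb_mean=self.mean,
            comb_modes=self.modes,
            comb_eigenvalues=self.eigenvalues,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CombinedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            if meta.get("format") != "kneestudy-appearance-model":
                raise ValueError(f"{path} is not an appearance model file")
            shape_model = ShapeModel(
                view=meta["view"],
                mean=z["shape_mean"],
                modes=z["shape_modes"],
                eigenvalues=z["shape_eigenvalues"],
                variance_retained=meta["shape_variance_retained"],
                total_variance=meta["shape_total_variance"],
            )
            tex_model = TextureModel(
                mean=z["tex_mean"],
                modes=z["tex_modes"],
                eigenvalues=z["tex_eigenvalues"],
                variance_retained=meta["texture_variance_retained"],
                total_variance=meta["texture_total_variance"],
            )
            frame = ReferenceFrame(
                ref_points=z["ref_points"],
                triangles=z["triangles"],
                sample_simplex=z["sample_simplex"],
                sample_bary=z["sample_bary"],
                frame_shape=tuple(meta["frame_shape"]),
                sample_pixels=z["sample_pixels"],
            )
            return cls(
                shape_model=shape_model,
                texture_model=tex_model,
                frame=frame,
                shape_weight=meta["shape_weight"],
                mean=z["comb_mean"],
                modes=z["comb_modes"],
                eigenvalues=z["comb_eigenvalues"],
                variance_retained=meta["variance_retained"],
                total_variance=meta["total_variance"],
            )


def build_combined_model(
    shape_model: ShapeModel,
    texture_model: TextureModel,
    shape_params: np.ndarray,
    texture_params: np.ndarray,
    frame: ReferenceFrame,
    variance_retained: float = 0.95,
) -> CombinedModel:
    """PCA of the variance-balanced concatenation ``[W_s b_s ; b_g]``.

    ``shape_params`` (n x t) and ``texture_params`` (n x s) must be paired
    per training example.
    """
    bs = np.atleast_2d(np.asarray(shape_params, dtype=float))
    bg = np.atleast_2d(np.asarray(texture_params, dtype=float))
    if bs.shape[0] != bg.shape[0]:
        raise ValueError(
            f"unpaired inputs: {bs.shape[0]} shape vs {bg.shape[0]} texture examples"
        )
    shape_var = float(shape_model.eigenvalues.sum())
    tex_var = float(texture_model.eigenvalues.sum())
    # degenerate blocks (no shape or no texture variance) make the
    # balancing weight moot; fall back to 1 so the other block survives
    w_s = (
        float(np.sqrt(tex_var / shape_var))
        if shape_var > 0 and tex_var > 0
        else 1.0
    )
    concat = np.hstack([w_s * bs, bg])
    mean, modes, lam, total = _pca(concat, variance_retained)
    return CombinedModel(
        shape_model=shape_model,
        texture_model=texture_model,
        frame=frame,
        shape_weight=w_s,
        mean=mean,
        modes=modes,
        eigenvalues=lam,
        variance_retained=variance_retained,
        total_variance=total,
    )


@dataclass
class AppearanceFeatures:
    c: np.ndarray      # combined appearance parameters
    b_s: np.ndarray    # shape-only parameters
    b_g: np.ndarray    # texture-only parameters


def extract_appearance_features(
    image: np.ndarray,
    landmarks: LandmarkSet,
    model: CombinedModel,
) -> AppearanceFeatures:
    """Deterministic (image, landmarks) -> appearance parameter vectors."""
    b_s, _pose = shape_to_params(landmarks, model.shape_model)
    g = warp_to_reference(image, landmarks, model.frame)
    b_g = model.texture_model.project(normalize_texture(g))
    concat = np.concatenate([model.shape_weight * b_s, b_g])
    c = model.modes.T @ (concat - model.mean)
    return AppearanceFeatures(c=c, b_s=b_s, b_g=b_g)


def train_appearance_model(
    images: list[np.ndarray],
    landmark_sets: list[LandmarkSet],
    variance_retained: float = 0.95,
    frame_width: int = 128,
) -> CombinedModel:
    """End-to-end training: Procrustes + shape PCA, warp + texture PCA,
    combined PCA, all from (image, landmarks) pairs."""
    from .shape import build_shape_model, procrustes_align

    aligned, mean_shape, _ = procrustes_align(landmark_sets)
    shape_model = build_shape_model(aligned, variance_retained)
    frame = build_reference_frame(shape_model.mean_shape, frame_width)
    textures = [
        normalize_texture(warp_to_reference(img, lms, frame))
        for img, lms in zip(images, landmark_sets)
    ]
    tex_model = build_texture_model(textures, variance_retained, normalized=True)
    bs = np.stack([shape_to_params(l, shape_model)[0] for l in landmark_sets])
    bg = np.stack([tex_model.project(t) for t in textures])
    return build_combined_model(
        shape_model, tex_model, bs, bg, frame, variance_retained
    )
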