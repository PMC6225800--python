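"""Schematic knee-radiograph rendering with known ground-truth landmarks.

Each view has a fixed template: smooth bone outlines (cubic-spline
resampled control polygons) carrying exactly the per-view landmark
topology.  A one-dimensional latent osteoarthritis severity drives the
deformations radiologists grade on real films:

* tibiofemoral joint-space narrowing — the tibia translates toward the
  femur as severity rises;
* marginal osteophytes — outward bump displacements at joint-margin
  landmarks, present only for positive severity;
* subchondral sclerosis — a severity-scaled bright band under the tibial
  plateau.

Rendering is deliberately schematic (bright ridges on a noisy background),
not photorealistic; it exists to give patch regressors and texture models
real edge structure with exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.draw import line as draw_line

from .landmarks import LATERAL, PA, LandmarkSet, subshape_slices

MIN_IMAGE_SIZE = 64
#: fraction of the image the template spans
_TEMPLATE_SPAN = 0.82

# severity scaling, in fractions of the image size
GAP_NARROW_PER_SD = 0.020     # tibial upward shift per severity SD
MIN_GAP_FRACTION = 0.015      # the joint space never fully closes
OSTEOPHYTE_PER_SD = 0.012     # marginal bump magnitude per positive SD
RIDGE_SIGMA_PX = 1.8
RIDGE_AMPLITUDE = 0.65
SCLEROSIS_MAX_AMPLITUDE = 0.35


def _resample(ctrl: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    ctrl = np.asarray(ctrl, dtype=float)
    k = min(3, len(ctrl) - 1)
    if closed:
        tck, _ = splprep([ctrl[:, 0], ctrl[:, 1]], s=0, per=True, k=k)
        u = np.linspace(0, 1, n, endpoint=False)
    else:
        tck, _ = splprep([ctrl[:, 0], ctrl[:, 1]], s=0, k=k)
        u = np.linspace(0, 1, n)
    x, y = splev(u, tck)
    return np.column_stack([x, y])


@dataclass(frozen=True)
class ViewTemplate:
    """Template landmark geometry (unit coordinates) plus severity anatomy."""

    view: str
    points: np.ndarray                    # (N, 2) in [0, 1]^2
    gap_pairs: tuple[tuple[int, int], ...]  # (femur_idx, tibia_idx) global
    osteophyte_sites: tuple[int, ...]     # global indices of marginal points
    closed_subshapes: tuple[str, ...]


def _pa_unit_points() -> np.ndarray:
    femur = _resample(
        [
            (0.30, 0.05), (0.28, 0.22), (0.21, 0.38), (0.24, 0.48),
            (0.30, 0.525), (0.40, 0.50), (0.47, 0.455), (0.53, 0.455),
            (0.60, 0.50), (0.70, 0.525), (0.76, 0.48), (0.79, 0.38),
            (0.72, 0.22), (0.70, 0.05),
        ],
        37,
    )
    tibia = _resample(
        [
            (0.31, 0.95), (0.27, 0.78), (0.20, 0.645), (0.30, 0.615),
            (0.43, 0.585), (0.50, 0.62), (0.57, 0.585), (0.70, 0.615),
            (0.80, 0.645), (0.73, 0.78), (0.69, 0.95),
        ],
        37,
    )
    return np.vstack([femur, tibia])


def _lateral_unit_points() -> np.ndarray:
    # patella: closed oval anterior to the condyles
    th = np.linspace(0, 2 * np.pi, 9, endpoint=False)
    patella_ctrl = np.column_stack(
        [0.20 + 0.055 * np.cos(th) + 0.015 * np.sin(th),
         0.33 + 0.115 * np.sin(th)]
    )
    patella = _resample(patella_ctrl, 21, closed=True)
    lat_condyle = _resample(
        [
            (0.40, 0.08), (0.37, 0.25), (0.38, 0.42), (0.45, 0.54),
            (0.56, 0.575), (0.66, 0.52), (0.70, 0.38), (0.67, 0.20),
            (0.63, 0.08),
        ],
        24,
    )
    med_condyle = _resample(
        [
            (0.46, 0.11), (0.43, 0.28), (0.45, 0.45), (0.52, 0.555),
            (0.62, 0.585), (0.71, 0.53), (0.745, 0.40), (0.72, 0.22),
            (0.68, 0.11),
        ],
        25,
    )
    tibia = _resample(
        [
            (0.42, 0.95), (0.39, 0.80), (0.355, 0.685), (0.45, 0.655),
            (0.58, 0.645), (0.70, 0.655), (0.80, 0.675), (0.76, 0.80),
            (0.72, 0.95),
        ],
        32,
    )
    return np.vstack([patella, lat_condyle, med_condyle, tibia])


def _compute_gap_pairs(view: str, pts: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Designated femur/tibia landmark pairs spanning the joint space.

    The lowest-quartile femur points are each paired with the tibia
    plateau point nearest in x.
    """
    slc = subshape_slices(view)
    femur = slc["femur"]
    tibia = slc["tibia"]
    fy = pts[femur, 1]
    fem_low = femur[fy >= np.quantile(fy, 0.75)]
    ty = pts[tibia, 1]
    plateau = tibia[ty <= np.quantile(ty, 0.30)]
    pairs = []
    for fi in fem_low:
        ti = plateau[np.argmin(np.abs(pts[plateau, 0] - pts[fi, 0]))]
        pairs.append((int(fi), int(ti)))
    return tuple(pairs)


def _compute_osteophyte_sites(view: str, pts: np.ndarray) -> tuple[int, ...]:
    """Joint-margin landmarks that grow marginal osteophyte bumps."""
    slc = subshape_slices(view)
    sites: list[int] = []
    femur = slc["femur"]
    fy = pts[femur, 1]
    low = femur[fy >= np.quantile(fy, 0.60)]
    sites.append(int(low[np.argmin(pts[low, 0])]))   # lateral femoral margin
    sites.append(int(low[np.argmax(pts[low, 0])]))   # medial femoral margin
    tibia = slc["tibia"]
    ty = pts[tibia, 1]
    plateau = tibia[ty <= np.quantile(ty, 0.30)]
    sites.append(int(plateau[np.argmin(pts[plateau, 0])]))
    sites.append(int(plateau[np.argmax(pts[plateau, 0])]))
    if view == LATERAL:
        patella = slc["patella"]
        sites.append(int(patella[np.argmin(pts[patella, 1])]))  # superior pole
        sites.append(int(patella[np.argmax(pts[patella, 1])]))  # inferior pole
    return tuple(sites)


@lru_cache(maxsize=None)
def view_template(view: str) -> ViewTemplate:
    """The frozen unit-coordinate template for a view."""
    if view == PA:
        pts = _pa_unit_points()
        closed: tuple[str, ...] = ()
    elif view == LATERAL:
        pts = _lateral_unit_points()
        closed = ("patella",)
    else:
        raise ValueError(f"unknown view {view!r}")
    return ViewTemplate(
        view=view,
        points=pts,
        gap_pairs=_compute_gap_pairs(view, pts),
        osteophyte_sites=_compute_osteophyte_sites(view, pts),
        closed_subshapes=closed,
    )


def template_landmarks(view: str, image_size: int) -> LandmarkSet:
    """Template mean shape scaled into an image of the given size."""
    if image_size < MIN_IMAGE_SIZE:
        raise ValueError(
            f"image_size {image_size} too small to contain the {view} "
            f"template; minimum is {MIN_IMAGE_SIZE}"
        )
    unit = view_template(view).points
    pts = (unit - 0.5) * (_TEMPLATE_SPAN * image_size) + image_size / 2.0
    return LandmarkSet(view, pts)


def tibiofemoral_gap(lms: LandmarkSet) -> float:
    """Mean vertical femur-to-tibia distance over the designated gap pairs."""
    tpl = view_template(lms.view)
    f_idx = np.array([p[0] for p in tpl.gap_pairs])
    t_idx = np.array([p[1] for p in tpl.gap_pairs])
    return float(np.mean(lms.points[t_idx, 1] - lms.points[f_idx, 1]))


def _deform_for_severity(
    pts: np.ndarray, view: str, severity: float, image_size: int
) -> np.ndarray:
    tpl = view_template(view)
    slc = subshape_slices(view)
    pts = pts.copy()
    # joint space narrowing: shift the whole tibia toward the femur,
    # clamped so the gap stays open
    f_idx = np.array([p[0] for p in tpl.gap_pairs])
    t_idx = np.array([p[1] for p in tpl.gap_pairs])
    gap = float(np.mean(pts[t_idx, 1] - pts[f_idx, 1]))
    shift = GAP_NARROW_PER_SD * image_size * severity
    shift = min(shift, gap - MIN_GAP_FRACTION * image_size)
    pts[slc["tibia"], 1] -= shift
    # marginal osteophytes for positive severity: outward radial bumps
    mag = OSTEOPHYTE_PER_SD * image_size * max(severity, 0.0)
    if mag > 0:
        sub_of = {}
        for name, idx in slc.items():
            if name in dict(COMPOSITES.get(view, {})):
                continue
            for i in idx:
                sub_of[int(i)] = name
        for site in tpl.osteophyte_sites:
            name = sub_of[site]
            idx = slc[name]
            centroid = pts[idx].mean(axis=0)
            d = pts[site] - centroid
            d /= max(np.linalg.norm(d), 1e-9)
            pos = int(np.where(idx == site)[0][0])
            for off, w in ((-1, 0.5), (0, 1.0), (1, 0.5)):
                j = pos + off
                if 0 <= j < len(idx):
                    pts[idx[j]] += w * mag * d
    return pts


# stored (non-composite) subshape names per view, for the deformation loop
COMPOSITES = {LATERAL: {"femur": None}, PA: {}}


def _apply_shape_jitter(
    pts: np.ndarray,
    view: str,
    rng: np.random.Generator,
    image_size: int,
    scale: float,
) -> np.ndarray:
    """Random pose + smooth per-bone variation emulating between-subject
    anatomy and positioning differences."""
    slc = subshape_slices(view)
    centre = np.array([image_size / 2.0, image_size / 2.0])
    s = 1.0 + 0.04 * rng.standard_normal() * scale
    theta = 0.03 * rng.standard_normal() * scale
    t = 0.03 * image_size * rng.standard_normal(2) * scale
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -sn], [sn, c]])
    out = (pts - centre) @ (s * rot).T + centre + t
    for name, _n in sorted((k, len(v)) for k, v in slc.items()):
        if name in COMPOSITES.get(view, {}):
            continue
        idx = slc[name]
        n = len(idx)
        # rigid per-bone jitter
        out[idx] += 0.008 * image_size * rng.standard_normal(2) * scale
        # one smooth sinusoidal bending mode per bone and axis
        tpar = np.linspace(0.0, 1.0, n)
        for axis in (0, 1):
            amp = 0.006 * image_size * rng.standard_normal() * scale
            phase = rng.uniform(0, 2 * np.pi)
            out[idx, axis] += amp * np.sin(2 * np.pi * tpar + phase)
    return out


def _rasterise_ridges(
    pts: np.ndarray, view: str, image_size: int
) -> np.ndarray:
    tpl = view_template(view)
    slc = subshape_slices(view)
    mask = np.zeros((image_size, image_size), dtype=bool)
    for name, _ in sorted(slc.items()):
        if name in COMPOSITES.get(view, {}):
            continue
        idx = slc[name]
        poly = pts[idx]
        closed = name in tpl.closed_subshapes
        pairs = zip(poly, np.roll(poly, -1, axis=0)) if closed else zip(poly[:-1], poly[1:])
        for a, b in pairs:
            r0, c0 = int(round(a[1])), int(round(a[0]))
            r1, c1 = int(round(b[1])), int(round(b[0]))
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < image_size) & (cc >= 0) & (cc < image_size)
            mask[rr[ok], cc[ok]] = True
    dist = ndimage.distance_transform_edt(~mask)
    return RIDGE_AMPLITUDE * np.exp(-(dist**2) / (2 * RIDGE_SIGMA_PX**2))


def _sclerosis_band(
    pts: np.ndarray, view: str, severity: float, image_size: int
) -> np.ndarray:
    from scipy.special import expit

    slc = subshape_slices(view)
    tib = pts[slc["tibia"]]
    plateau = tib[tib[:, 1] <= np.quantile(tib[:, 1], 0.30)]
    y0 = plateau[:, 1].mean() + 0.02 * image_size
    x_lo, x_hi = plateau[:, 0].min(), plateau[:, 0].max()
    amp = SCLEROSIS_MAX_AMPLITUDE * float(expit(1.3 * severity))
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    band = np.exp(-((yy - y0) ** 2) / (2 * (0.015 * image_size) ** 2))
    win = expit((xx - x_lo) / 2.0) * expit((x_hi - xx) / 2.0)
    return amp * band * win


def render_knee(
    severity: float,
    view: str,
    image_size: int,
    rng: np.random.Generator,
    shape_jitter_scale: float = 1.0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, LandmarkSet]:
    """Render one synthetic knee; returns (float image in [0,1], landmarks).

    With ``severity=0``, ``shape_jitter_scale=0`` the landmarks equal the
    scaled template exactly.
    """
    base = template_landmarks(view, image_size).points
    pts = _deform_for_severity(base, view, severity, image_size)
    pts = _apply_shape_jitter(pts, view, rng, image_size, shape_jitter_scale)
    img = 0.18 + noise_sd * rng.standard_normal((image_size, image_size))
    img += _rasterise_ridges(pts, view, image_size)
    img += _sclerosis_band(pts, view, severity, image_size)
    np.clip(img, 0.0, 1.0, out=img)
    return img, LandmarkSet(view, pts)
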