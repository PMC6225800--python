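"""Landmark sets and the per-view point topologies.

Two radiographic views are modelled.  The lateral view uses four bone
outlines — patella (21 points), lateral femoral condyle (24), medial
femoral condyle (25) and tibia (32), 102 points in total, with the femur
defined as the union of the two condyles (49 points).  The posteroanterior
(PA) view uses two outlines — femur and tibia, 37 points each, 74 total.

Coordinates are 0-based pixel centres in image convention: x grows
rightward, y grows downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PA = "PA"
LATERAL = "LATERAL"

#: subshape name -> point count, in storage order, per view
TOPOLOGIES: dict[str, tuple[tuple[str, int], ...]] = {
    PA: (("femur", 37), ("tibia", 37)),
    LATERAL: (
        ("patella", 21),
        ("lateral_femoral_condyle", 24),
        ("medial_femoral_condyle", 25),
        ("tibia", 32),
    ),
}

#: subshapes defined as unions of stored ones
COMPOSITE_SUBSHAPES: dict[str, dict[str, tuple[str, ...]]] = {
    PA: {},
    LATERAL: {"femur": ("lateral_femoral_condyle", "medial_femoral_condyle")},
}


def view_n_points(view: str) -> int:
    """Total landmark count for a view (74 for PA, 102 for lateral)."""
    return sum(n for _, n in TOPOLOGIES[view])


def subshape_slices(view: str) -> dict[str, np.ndarray]:
    """Index arrays of every subshape (including composites) for a view."""
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, n in TOPOLOGIES[view]:
        out[name] = np.arange(start, start + n)
        start += n
    for name, parts in COMPOSITE_SUBSHAPES[view].items():
        out[name] = np.concatenate([out[p] for p in parts])
    return out


@dataclass
class LandmarkSet:
    """An ordered 2-D point configuration conforming to a view topology."""

    view: str
    points: np.ndarray  # (N, 2) float array, columns (x, y)
    closed_subshapes: tuple[str, ...] = field(default=("patella",))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.view not in TOPOLOGIES:
            raise ValueError(f"unknown view {self.view!r}; expected PA or LATERAL")
        expected = view_n_points(self.view)
        if self.points.shape != (expected, 2):
            raise ValueError(
                f"view {self.view} requires {expected} points, "
                f"got array of shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def subshape(self, name: str) -> np.ndarray:
        """Points of a named subshape (copy)."""
        idx = subshape_slices(self.view).get(name)
        if idx is None:
            raise KeyError(f"view {self.view} has no subshape {name!r}")
        return self.points[idx].copy()

    def subshape_indices(self, name: str) -> np.ndarray:
        idx = subshape_slices(self.view).get(name)
        if idx is None:
            raise KeyError(f"view {self.view} has no subshape {name!r}")
        return idx.copy()

    def as_vector(self) -> np.ndarray:
        """Flatten to (2N,) in x0,y0,x1,y1,... order."""
        return self.points.reshape(-1).copy()

    @classmethod
    def from_vector(cls, view: str, vec: np.ndarray) -> "LandmarkSet":
        vec = np.asarray(vec, dtype=float)
        return cls(view=view, points=vec.reshape(-1, 2))

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.view, self.points.copy())


def write_points(path: str | Path, lms: LandmarkSet) -> None:
    """Write the plain-text points format::

        n_points: N
        {
        x y
        ...
        }
    """
    lines = [f"n_points: {lms.n_points}", "{"]
    lines += [f"{x:.4f} {y:.4f}" for x, y in lms.points]
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_points(path: str | Path, view: str | None = None) -> LandmarkSet:
    """Read a points file; the view is inferred from the count if omitted."""
    tokens = Path(path).read_text().split("\n")
    tokens = [t.strip() for t in tokens if t.strip()]
    if not tokens or not tokens[0].startswith("n_points:"):
        raise ValueError(f"{path}: missing 'n_points:' header")
    n = int(tokens[0].split(":")[1])
    body = [t for t in tokens[1:] if t not in ("{", "}")]
    if len(body) != n:
        raise ValueError(f"{path}: header says {n} points, found {len(body)}")
    pts = np.array([[float(v) for v in line.split()] for line in body])
    if view is None:
        by_count = {view_n_points(v): v for v in TOPOLOGIES}
        if n not in by_count:
            raise ValueError(f"{path}: {n} points matches no known view topology")
        view = by_count[n]
    return LandmarkSet(view=view, points=pts)
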