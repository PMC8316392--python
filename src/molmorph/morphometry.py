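"""Muscle morphometry: segmentation, maximum-caliper (Feret) diameters and
the standardized size ratio F_A/F_B.

The measurement protocol mirrors standard fluorescence-image muscle
morphometry: threshold the phalloidin channel at a fraction of the maximum
intensity (default 14%), label 8-connected components, and for each
hemisegment record the Feret diameter of the longest muscle (the candidate
muscle-of-Lawrence analog, ``F_A``) and of the medial-most longitudinal
muscle (the control, ``F_B``).  The dimensionless ratio ``F_A/F_B`` is the
quantity carried into the statistics; it is invariant to magnification and
may fall below 1 when the medial muscle happens to be the longest.

The Feret diameter is the longest distance between any two boundary points
(maximum caliper).  It is computed exactly via an Andrew monotone-chain
convex hull followed by rotating calipers, O(n log n) overall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "BoundaryPointSet",
    "LabeledMuscleSet",
    "MuscleComponent",
    "HemisegmentMeasurement",
    "InsufficientObjectsError",
    "convex_hull",
    "rotating_calipers_diameter",
    "feret_diameter",
    "segment_muscles",
    "select_candidate_and_control",
    "standardized_ratio",
]


class InsufficientObjectsError(ValueError):
    """Raised when fewer muscle objects than required are present."""


@dataclass(frozen=True)
class BoundaryPointSet:
    """Ordered 2-D boundary coordinates of one muscle object.

    Coordinates are (row, col) pixel centers, 0-based.  When ``pixel_size``
    (physical length per pixel, e.g. µm/px) is given, derived lengths are
    reported in physical units; otherwise in pixels.
    """

    points: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("boundary needs at least 2 finite 2-D points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("boundary coordinates must be finite")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class MuscleComponent:
    label: int
    boundary: BoundaryPointSet
    centroid: tuple[float, float]  # (row, col)

    @property
    def feret(self) -> float:
        return feret_diameter(self.boundary)


@dataclass
class LabeledMuscleSet:
    """Segmented muscle objects of one image plus the dorsal-midline column."""

    components: list[MuscleComponent]
    image_shape: tuple[int, int]
    midline_x: float

    def __post_init__(self) -> None:
        labels = [c.label for c in self.components]
        if len(labels) != len(set(labels)):
            raise ValueError("component labels must be unique")
        nrow, ncol = self.image_shape
        for c in self.components:
            r, x = c.centroid
            if not (0 <= r < nrow and 0 <= x < ncol):
                raise ValueError(f"centroid of label {c.label} outside image")


@dataclass(frozen=True)
class HemisegmentMeasurement:
    """One muscle-pair measurement for one side of one segment of one fly."""

    fly_id: str
    species: str
    sex: str  # "male" | "female"
    segment: str  # "A4" | "A5"
    side: str  # "left" | "right"
    F_A: float
    F_B: float
    ratio: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.F_A <= 0 or self.F_B <= 0:
            raise ValueError("Feret diameters must be positive")
        if math.isnan(self.ratio):
            object.__setattr__(self, "ratio", self.F_A / self.F_B)
        elif not math.isclose(self.ratio, self.F_A / self.F_B, rel_tol=1e-9):
            raise ValueError("ratio inconsistent with F_A/F_B")


# ---------------------------------------------------------------------------
# exact maximum caliper


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain convex hull, counter-clockwise, no collinear
    interior vertices.  Degenerate inputs (all collinear) return the two
    extreme points."""
    pts = np.asarray(points, dtype=float)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] == 1:
        return uniq
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    p = uniq[order]

    def _half(seq):
        out: list[np.ndarray] = []
        for q in seq:
            while len(out) >= 2:
                o, a = out[-2], out[-1]
                cross = (a[0] - o[0]) * (q[1] - o[1]) - (a[1] - o[1]) * (q[0] - o[0])
                if cross <= 0:  # clockwise or collinear: drop
                    out.pop()
                else:
                    break
            out.append(q)
        return out

    lower = _half(p)
    upper = _half(p[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if hull.shape[0] < 2:  # all collinear
        return np.array([p[0], p[-1]])
    return hull


def rotating_calipers_diameter(hull: np.ndarray) -> float:
    """Diameter (max pairwise distance) of a convex polygon given in order.

    Classic antipodal-pair sweep: for each edge advance the opposite vertex
    while the supported triangle area keeps growing.
    """
    h = np.asarray(hull, dtype=float)
    m = h.shape[0]
    if m == 1:
        return 0.0
    if m == 2:
        return float(np.hypot(*(h[0] - h[1])))

    def area2(a, b, c) -> float:
        return abs(
            (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        )

    best = 0.0
    k = 1
    for i in range(m):
        j = (i + 1) % m
        while area2(h[i], h[j], h[(k + 1) % m]) > area2(h[i], h[j], h[k]):
            k = (k + 1) % m
        for q in (h[k], h[(k + 1) % m]):
            for p in (h[i], h[j]):
                d = math.hypot(p[0] - q[0], p[1] - q[1])
                if d > best:
                    best = d
    return best


def feret_diameter(boundary: BoundaryPointSet | np.ndarray) -> float:
    """Maximum Feret diameter (maximum caliper) of a point set.

    Exactly the maximum pairwise Euclidean distance; computed on the convex
    hull with rotating calipers.  Scaled by ``pixel_size`` when present.
    """
    if isinstance(boundary, BoundaryPointSet):
        pts, scale = boundary.points, boundary.pixel_size
    else:
        pts, scale = np.asarray(boundary, dtype=float), None
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("need at least 2 points")
    d = rotating_calipers_diameter(convex_hull(pts))
    return d * scale if scale is not None else d


# ---------------------------------------------------------------------------
# segmentation


def _component_boundary(mask: np.ndarray, pixel_size: float | None) -> BoundaryPointSet:
    # Outer boundary = component pixels not fully 8-surrounded by the
    # component.  Vertices at pixel centers; the Feret diameter only depends
    # on the convex hull, so interior pixels are redundant anyway.
    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3)))
    edge = mask & ~interior
    if not edge.any():
        edge = mask
    pts = np.argwhere(edge).astype(float)
    if pts.shape[0] < 2:  # single-pixel object: duplicate-ish corner points
        pts = np.vstack([pts, pts + [0.0, 0.0]])
    return BoundaryPointSet(points=pts, pixel_size=pixel_size)


def segment_muscles(
    image: np.ndarray,
    threshold_fraction: float = 0.14,
    *,
    min_area: int = 50,
    midline_x: float | None = None,
    pixel_size: float | None = None,
) -> LabeledMuscleSet:
    """Threshold an intensity image and return labeled muscle objects.

    Foreground = pixels >= ``threshold_fraction`` x max intensity (default
    14% of the maximum, the conventional setting for phalloidin-stained
    tergite preparations).  8-connected components smaller than ``min_area``
    pixels are discarded as speckle.  An empty foreground yields an empty
    component list, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise ValueError("image must be a non-empty 2-D array")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if midline_x is None:
        midline_x = (img.shape[1] - 1) / 2.0

    peak = img.max()
    components: list[MuscleComponent] = []
    if peak > 0:
        mask = img >= threshold_fraction * peak
        labeled = sk_label(mask, connectivity=2)
        for prop in regionprops(labeled):
            if prop.area < min_area:
                continue
            comp_mask = labeled == prop.label
            components.append(
                MuscleComponent(
                    label=int(prop.label),
                    boundary=_component_boundary(comp_mask, pixel_size),
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                )
            )
    return LabeledMuscleSet(
        components=components, image_shape=img.shape, midline_x=float(midline_x)
    )


def select_candidate_and_control(
    muscles: LabeledMuscleSet,
) -> tuple[MuscleComponent, MuscleComponent]:
    """Pick the candidate (longest Feret) and control (medial-most) muscles.

    The candidate is the component with the largest Feret diameter; the
    control is the component whose centroid column is nearest the dorsal
    midline.  If a single component fills both roles a warning is emitted
    (the returned pair then aliases one object).
    """
    if len(muscles.components) < 2:
        raise InsufficientObjectsError(
            f"need >= 2 muscle objects, found {len(muscles.components)}"
        )
    candidate = max(muscles.components, key=lambda c: c.feret)
    control = min(
        muscles.components, key=lambda c: abs(c.centroid[1] - muscles.midline_x)
    )
    if candidate.label == control.label:
        warnings.warn(
            "longest muscle is also the medial-most; candidate and control "
            "coincide",
            stacklevel=2,
        )
    return candidate, control


def standardized_ratio(F_A: float, F_B: float) -> float:
    """Standardized Feret diameter F_A/F_B (dimensionless, may be < 1)."""
    if F_A <= 0 or F_B <= 0:
        raise ValueError("Feret diameters must be positive")
    return F_A / F_B


def measure_image(
    image: np.ndarray,
    *,
    fly_id: str,
    species: str,
    sex: str,
    segment: str,
    side: str,
    threshold_fraction: float = 0.14,
    min_area: int = 50,
    midline_x: float | None = None,
    pixel_size: float | None = None,
) -> HemisegmentMeasurement:
    """End-to-end convenience: segment, select, measure one hemisegment."""
    muscles = segment_muscles(
        image,
        threshold_fraction,
        min_area=min_area,
        midline_x=midline_x,
        pixel_size=pixel_size,
    )
    candidate, control = select_candidate_and_control(muscles)
    fa, fb = candidate.feret, control.feret
    return HemisegmentMeasurement(
        fly_id=fly_id,
        species=species,
        sex=sex,
        segment=segment,
        side=side,
        F_A=fa,
        F_B=fb,
        ratio=standardized_ratio(fa, fb),
    )
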