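"""Reference-intensity measurement for signal normalization.

Surface-coil reception makes raw vessel-wall MR intensities incomparable
between patients and slices, so every pixel is expressed as a ratio to a
reference tissue before thresholding. Three references are supported:

* ``scm`` — mean intensity of the sternocleidomastoid muscle, restricted to
  the part falling inside a 4 cm circular ROI centred at the carotid lumen;
* ``adjacent_muscle`` — mean intensity of a nearby deep muscle (e.g. scalene)
  drawn to be isointense with normal carotid wall;
* ``local_median`` — median intensity inside the 4 cm ROI, which needs no
  manual muscle contour at all.

Pixel membership in any region is decided by the pixel-centre test: a pixel
belongs to a circle iff its centre lies within the radius, and to a polygon
iff its centre is inside under the even–odd rule with the half-open scan-line
boundary convention. Distances are computed in mm using the slice spacing, so
anisotropic pixels are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from shapely.geometry import Polygon

from .io import AnnotationSet, ImageSlice, ValidationError

__all__ = [
    "ReferenceKind",
    "ReferenceMeasurement",
    "rasterize_circle",
    "rasterize_polygon",
    "scm_reference",
    "adjacent_muscle_reference",
    "local_median_reference",
    "measure_reference",
    "DEFAULT_ROI_DIAMETER_MM",
]

DEFAULT_ROI_DIAMETER_MM = 40.0


class ReferenceKind(str, Enum):
    SCM = "scm"
    ADJACENT_MUSCLE = "adjacent_muscle"
    LOCAL_MEDIAN = "local_median"


@dataclass(frozen=True)
class ReferenceMeasurement:
    """A reference intensity, or an explicit 'not measurable on this slice'.

    ``valid=False`` (absent contour or empty mask) is a value, not an error:
    such slices are excluded from analyses using that reference, mirroring
    slices dropped when the SCM lies outside the 4 cm ROI.
    """

    kind: ReferenceKind
    value: float
    n_pixels: int
    valid: bool

    @classmethod
    def invalid(cls, kind: ReferenceKind) -> "ReferenceMeasurement":
        return cls(kind=kind, value=float("nan"), n_pixels=0, valid=False)


def _pixel_center_grids(template: ImageSlice) -> tuple[np.ndarray, np.ndarray]:
    """mm coordinates (X, Y) of every pixel centre: x along columns, y along rows."""
    nr, nc = template.pixels.shape
    sr, sc = template.spacing_mm
    ys = np.arange(nr) * sr
    xs = np.arange(nc) * sc
    return np.meshgrid(xs, ys)


def rasterize_circle(
    center: tuple[float, float], diameter_mm: float, template: ImageSlice
) -> np.ndarray:
    """Boolean mask of pixels whose centre lies within ``diameter_mm/2`` of ``center``.

    The centre may lie anywhere, including outside the image; an empty mask is
    a legal result.
    """
    if diameter_mm <= 0:
        raise ValidationError("circle diameter must be positive")
    X, Y = _pixel_center_grids(template)
    r = diameter_mm / 2.0
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= r * r


def rasterize_polygon(poly: np.ndarray, template: ImageSlice) -> np.ndarray:
    """Boolean mask of pixels whose centre is inside the polygon (even–odd rule).

    Boundary-touching centres follow the half-open ray-casting convention: a
    centre exactly on a lower/left edge counts as inside, on an upper/right
    edge as outside, so abutting polygons tile without double counting.
    """
    v = np.asarray(poly, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError("polygon needs >= 3 [x, y] vertices")
    sh = Polygon(v)
    if sh.area == 0:
        raise ValidationError("degenerate polygon (zero area)")
    if not sh.is_simple or not sh.is_valid:
        raise ValidationError("polygon is self-intersecting")

    X, Y = _pixel_center_grids(template)
    inside = np.zeros(X.shape, dtype=bool)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for i in range(len(v)):
        if y1[i] == y2[i]:  # horizontal edge: never crossed by a horizontal ray
            continue
        crosses = (y1[i] > Y) != (y2[i] > Y)
        x_at = (x2[i] - x1[i]) * (Y - y1[i]) / (y2[i] - y1[i]) + x1[i]
        inside ^= crosses & (X < x_at)
    return inside


def _mean_measurement(
    kind: ReferenceKind, pixels: np.ndarray, mask: np.ndarray
) -> ReferenceMeasurement:
    n = int(mask.sum())
    if n == 0:
        return ReferenceMeasurement.invalid(kind)
    return ReferenceMeasurement(kind=kind, value=float(pixels[mask].mean()), n_pixels=n, valid=True)


def scm_reference(
    s: ImageSlice, ann: AnnotationSet, roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM
) -> ReferenceMeasurement:
    """Mean SCM intensity inside the circular ROI centred at the lumen.

    Invalid (not an exception) when the SCM contour is absent or falls
    entirely outside the ROI — those slices are excluded from SCM-referenced
    analyses.
    """
    if ann.scm is None:
        return ReferenceMeasurement.invalid(ReferenceKind.SCM)
    mask = rasterize_polygon(ann.scm, s) & rasterize_circle(ann.lumen_center, roi_diameter_mm, s)
    return _mean_measurement(ReferenceKind.SCM, s.pixels, mask)


def adjacent_muscle_reference(s: ImageSlice, ann: AnnotationSet) -> ReferenceMeasurement:
    """Mean intensity inside the adjacent-muscle contour (already local; no ROI clip)."""
    if ann.adjacent_muscle is None:
        return ReferenceMeasurement.invalid(ReferenceKind.ADJACENT_MUSCLE)
    mask = rasterize_polygon(ann.adjacent_muscle, s)
    return _mean_measurement(ReferenceKind.ADJACENT_MUSCLE, s.pixels, mask)


def local_median_reference(
    s: ImageSlice, ann: AnnotationSet, roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM
) -> ReferenceMeasurement:
    """Median intensity inside the circular ROI (even counts: midpoint of the
    two central order statistics). An empty ROI is a hard error — the lumen
    centre is off-image."""
    mask = rasterize_circle(ann.lumen_center, roi_diameter_mm, s)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(
            f"slice {s.patient_id}/{s.slice_index}: circular ROI does not intersect the image"
        )
    return ReferenceMeasurement(
        kind=ReferenceKind.LOCAL_MEDIAN,
        value=float(np.median(s.pixels[mask])),
        n_pixels=n,
        valid=True,
    )


def measure_reference(
    s: ImageSlice,
    ann: AnnotationSet,
    kind: ReferenceKind | str,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> ReferenceMeasurement:
    """Dispatch on reference kind."""
    kind = ReferenceKind(kind)
    if kind is ReferenceKind.SCM:
        return scm_reference(s, ann, roi_diameter_mm)
    if kind is ReferenceKind.ADJACENT_MUSCLE:
        return adjacent_muscle_reference(s, ann)
    return local_median_reference(s, ann, roi_diameter_mm)
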