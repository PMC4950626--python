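"""Per-slice IPH segmentation by normalized-intensity thresholding.

A pixel inside the outer-wall contour is labelled hemorrhage when its
intensity strictly exceeds ``threshold × reference``. No morphology or
connected-component cleanup is applied — the method is pure thresholding.
The per-slice detection *score* (max normalized intensity over the wall
region) is the scalar whose comparison with any threshold reproduces the
presence call, which is what the ROC sweep operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnnotationSet, ImageSlice, ValidationError
from .reference import ReferenceMeasurement, rasterize_polygon

__all__ = ["DetectionResult", "detect_iph", "slice_score"]


@dataclass
class DetectionResult:
    """Binary IPH mask plus presence flag and physical area for one slice."""

    threshold: float
    reference: ReferenceMeasurement
    mask: np.ndarray
    presence: bool
    area_mm2: float
    max_norm_intensity: float


def _wall_mask(s: ImageSlice, ann: AnnotationSet) -> np.ndarray:
    mask = rasterize_polygon(ann.outer_wall, s)
    if not mask.any():
        raise ValidationError(
            f"slice {s.patient_id}/{s.slice_index}: outer-wall contour covers no pixel centre"
        )
    return mask


def detect_iph(
    s: ImageSlice,
    ann: AnnotationSet,
    ref: ReferenceMeasurement,
    threshold: float,
    min_area_mm2: float = 0.0,
) -> DetectionResult:
    """Threshold normalized intensity inside the outer wall.

    ``min_area_mm2`` (default 0: any supra-threshold pixel counts) lets a
    caller impose a minimum lesion size; the method itself defines none.
    """
    if not ref.valid:
        raise ValidationError("invalid reference: slice should have been excluded by the caller")
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    wall = _wall_mask(s, ann)
    norm = s.pixels / ref.value
    mask = wall & (norm > threshold)
    area = float(mask.sum()) * s.pixel_area_mm2
    return DetectionResult(
        threshold=float(threshold),
        reference=ref,
        mask=mask,
        presence=area > min_area_mm2,
        area_mm2=area,
        max_norm_intensity=float(norm[wall].max()),
    )


def slice_score(s: ImageSlice, ann: AnnotationSet, ref: ReferenceMeasurement) -> float:
    """Max normalized intensity over the outer-wall region.

    For every threshold t, ``detect_iph(...).presence == (slice_score > t)``,
    so this scalar drives the ROC analysis.
    """
    if not ref.valid:
        raise ValidationError("invalid reference: slice should have been excluded by the caller")
    wall = _wall_mask(s, ann)
    return float((s.pixels[wall] / ref.value).max())
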