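"""Histology-to-MR slice matching and analysis-subset filtering.

Histology sections are fused onto MR slices by longitudinal position (signed
distance to the carotid bifurcation). An MR slice is thicker than a histology
section, so several sections may land on one slice: IPH is called present if
*any* matched section shows it, and the truth area is the mean over all
matched sections. Analysis subsets then optionally drop positive slices with
small IPH (area below pi*(0.63*x)^2 mm^2 for x = 1 or 1.5, 0.63 mm being the
acquired in-plane resolution) and/or heavily (>50%) calcified IPH — both
regimes where gradient-echo imaging is physically handicapped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .io import AnnotationSet, HistologySection, ImageSlice, ValidationError

__all__ = [
    "MatchedSlice",
    "SubsetSpec",
    "match_sections",
    "apply_subset",
    "area_cutoff",
    "DEFAULT_HALF_WINDOW_MM",
    "ACQUIRED_RESOLUTION_MM",
]

log = logging.getLogger(__name__)

# Half the 1 mm MR slice thickness: nearest-slab assignment window.
DEFAULT_HALF_WINDOW_MM = 0.5
# Acquired (not reconstructed) in-plane resolution pinning the small-IPH cutoff.
ACQUIRED_RESOLUTION_MM = 0.63


@dataclass
class MatchedSlice:
    """An MR slice with fused histology ground truth."""

    slice: ImageSlice
    ann: AnnotationSet
    truth_present: bool
    truth_area_mm2: float
    truth_calcified_fraction: float
    n_sections: int


@dataclass(frozen=True)
class SubsetSpec:
    """One analysis subset: minimum IPH area and the calcification exclusion."""

    min_iph_area_mm2: float = 0.0
    exclude_heavily_calcified: bool = False
    calcified_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.min_iph_area_mm2 < 0:
            raise ValidationError("min_iph_area_mm2 must be >= 0")
        if not 0 < self.calcified_cutoff <= 1:
            raise ValidationError("calcified_cutoff must lie in (0, 1]")

    @property
    def label(self) -> str:
        ca = "no_ca" if self.exclude_heavily_calcified else "with_ca"
        return f"area>{self.min_iph_area_mm2:g}_{ca}"


def area_cutoff(x: float, acquired_resolution_mm: float = ACQUIRED_RESOLUTION_MM) -> float:
    """Small-IPH area cutoff pi * (resolution * x)^2 in mm^2.

    With the 0.63 mm acquired resolution, x = 1 gives 1.2469 mm^2 (printed as
    1.25) and x = 1.5 gives 2.8055 mm^2 (printed as 2.80).
    """
    if x <= 0 or acquired_resolution_mm <= 0:
        raise ValidationError("area_cutoff arguments must be positive")
    return math.pi * (acquired_resolution_mm * x) ** 2


def match_sections(
    slices: list[tuple[ImageSlice, AnnotationSet]],
    sections: list[HistologySection],
    half_window_mm: float = DEFAULT_HALF_WINDOW_MM,
) -> list[MatchedSlice]:
    """Assign each section to its nearest same-patient slice within the window.

    Each section goes to at most one slice. Slices that attract no section are
    logged and dropped; sections falling outside every slice's window are
    logged as unassigned. The fused calcified fraction is the IPH-area-weighted
    mean over matched sections (0 when the pooled area is 0).
    """
    if half_window_mm <= 0:
        raise ValidationError("half_window_mm must be positive")
    seen: set[tuple[str, float]] = set()
    for sec in sections:
        key = (sec.patient_id, sec.position_mm)
        if key in seen:
            raise ValidationError(f"duplicate histology section for {key}")
        seen.add(key)

    assigned: dict[int, list[HistologySection]] = {i: [] for i in range(len(slices))}
    n_unassigned = 0
    for sec in sections:
        best_i, best_d = None, float("inf")
        for i, (img, _) in enumerate(slices):
            if img.patient_id != sec.patient_id:
                continue
            d = abs(img.position_mm - sec.position_mm)
            if d < best_d:
                best_i, best_d = i, d
        if best_i is not None and best_d <= half_window_mm:
            assigned[best_i].append(sec)
        else:
            n_unassigned += 1
            log.info(
                "histology section %s@%gmm unassigned (nearest slice %.3g mm away)",
                sec.patient_id,
                sec.position_mm,
                best_d,
            )

    matched: list[MatchedSlice] = []
    for i, (img, ann) in enumerate(slices):
        secs = assigned[i]
        if not secs:
            log.info("slice %s/%d has no matched histology; dropped", img.patient_id, img.slice_index)
            continue
        total_area = sum(s.iph_area_mm2 for s in secs)
        frac = (
            sum(s.iph_area_mm2 * s.calcified_fraction for s in secs) / total_area
            if total_area > 0
            else 0.0
        )
        matched.append(
            MatchedSlice(
                slice=img,
                ann=ann,
                truth_present=any(s.iph_present for s in secs),
                truth_area_mm2=total_area / len(secs),
                truth_calcified_fraction=frac,
                n_sections=len(secs),
            )
        )
    log.info(
        "matched %d/%d slices; %d/%d sections unassigned",
        len(matched),
        len(slices),
        n_unassigned,
        len(sections),
    )
    return matched


def keeps(m: MatchedSlice, spec: SubsetSpec) -> bool:
    """Subset membership predicate. IPH-absent slices are always kept."""
    if not m.truth_present:
        return True
    if m.truth_area_mm2 < spec.min_iph_area_mm2:
        return False
    if spec.exclude_heavily_calcified and m.truth_calcified_fraction > spec.calcified_cutoff:
        return False
    return True


def apply_subset(matched: list[MatchedSlice], spec: SubsetSpec) -> list[MatchedSlice]:
    """Filter to the analysis subset; never mutates retained slices."""
    return [m for m in matched if keeps(m, spec)]
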