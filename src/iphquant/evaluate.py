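"""Patient-level leave-one-out cross-validation and headline metrics.

Each patient's slices are classified with the Youden-optimal threshold fitted
on all *other* patients (folds iterated with sklearn's ``LeaveOneGroupOut``),
and the held-out predictions are pooled before computing sensitivity,
specificity and the Pearson correlation between detected and histology IPH
areas. Pooling (micro-averaging) is used rather than per-fold averaging
because single-patient folds frequently lack one class.

The area correlation is reported twice — over all included slices and over
truth-positive slices only — because a slice-level r can be inflated by the
many (0, 0) pairs from IPH-absent slices; the positive-only value is the
primary one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import LeaveOneGroupOut

from .io import ValidationError
from .matching import MatchedSlice, SubsetSpec, apply_subset
from .optimize import DEFAULT_GRID_STEP, roc_from_scores, youden_optimal, ThresholdChoice
from .reference import DEFAULT_ROI_DIAMETER_MM, ReferenceKind, measure_reference
from .detection import _wall_mask

__all__ = [
    "ScoredSlice",
    "CvReport",
    "score_slices",
    "optimize_full",
    "loocv",
    "pearson_r",
    "confusion_metrics",
]

log = logging.getLogger(__name__)


@dataclass
class ScoredSlice:
    """A matched slice with its reference value, detection score and the
    sorted normalized wall intensities (for O(log n) area-at-threshold)."""

    matched: MatchedSlice
    ref_kind: ReferenceKind
    ref_value: float
    score: float
    sorted_norm: np.ndarray = field(repr=False)

    @property
    def patient_id(self) -> str:
        return self.matched.slice.patient_id

    def area_at(self, threshold: float) -> float:
        """Detected IPH area (mm^2) at the given normalized-intensity cutoff."""
        n_above = self.sorted_norm.size - np.searchsorted(self.sorted_norm, threshold, side="right")
        return float(n_above) * self.matched.slice.pixel_area_mm2


@dataclass
class CvReport:
    """Pooled LOOCV performance for one reference x subset combination."""

    reference_kind: ReferenceKind
    subset: SubsetSpec
    fold_thresholds: dict[str, float]
    pooled_sensitivity: float
    pooled_specificity: float
    pearson_r_all: float
    pearson_r_positive: float
    n_slices: int
    n_positive: int

    @property
    def threshold_spread(self) -> float:
        """max - min of fold thresholds: the robustness diagnostic."""
        vals = list(self.fold_thresholds.values())
        return max(vals) - min(vals)


def pearson_r(x, y) -> float:
    """Product-moment correlation; zero variance yields NaN with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("pearson_r needs equal-length vectors with >= 3 items")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("pearson_r undefined: zero variance in one vector", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def confusion_metrics(pred, truth) -> tuple[float, float, float]:
    """(sensitivity, specificity, Youden J) of boolean predictions vs truth."""
    pred = np.asarray(pred, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValidationError("truth must contain both classes")
    sens = float(pred[truth].mean())
    spec = float((~pred[~truth]).mean())
    return sens, spec, sens + spec - 1.0


def score_slices(
    matched: list[MatchedSlice],
    ref_kind: ReferenceKind | str,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> list[ScoredSlice]:
    """Measure the reference and detection score on every matched slice.

    Slices whose reference is invalid (e.g. SCM outside the ROI) are logged
    and excluded from the returned dataset.
    """
    ref_kind = ReferenceKind(ref_kind)
    out: list[ScoredSlice] = []
    n_excluded = 0
    for m in matched:
        ref = measure_reference(m.slice, m.ann, ref_kind, roi_diameter_mm)
        if not ref.valid:
            n_excluded += 1
            log.info(
                "slice %s/%d excluded: %s reference not measurable",
                m.slice.patient_id,
                m.slice.slice_index,
                ref_kind.value,
            )
            continue
        wall = _wall_mask(m.slice, m.ann)
        norm = np.sort(m.slice.pixels[wall] / ref.value)
        out.append(
            ScoredSlice(
                matched=m,
                ref_kind=ref_kind,
                ref_value=ref.value,
                score=float(norm[-1]),
                sorted_norm=norm,
            )
        )
    if n_excluded:
        log.info("%d/%d slices excluded for reference %s", n_excluded, len(matched), ref_kind.value)
    return out


def _subset(scored: list[ScoredSlice], spec: SubsetSpec) -> list[ScoredSlice]:
    kept_matched = {id(m) for m in apply_subset([s.matched for s in scored], spec)}
    return [s for s in scored if id(s.matched) in kept_matched]


def optimize_full(
    scored: list[ScoredSlice], subset: SubsetSpec, grid_step: float = DEFAULT_GRID_STEP
) -> tuple[ThresholdChoice, float, int, int]:
    """Full-data ROC + Youden optimum on one subset.

    Returns (choice, auc, n_positive, n_total).
    """
    data = _subset(scored, subset)
    scores = [s.score for s in data]
    labels = [s.matched.truth_present for s in data]
    roc = roc_from_scores(scores, labels)
    return youden_optimal(roc, grid_step), roc.auc, roc.n_positive, len(data)


def loocv(
    scored: list[ScoredSlice],
    subset: SubsetSpec,
    grid_step: float = DEFAULT_GRID_STEP,
) -> CvReport:
    """Patient-level leave-one-out cross-validation on one analysis subset."""
    data = _subset(scored, subset)
    patients = np.array([s.patient_id for s in data])
    if np.unique(patients).size < 2:
        raise ValidationError("LOOCV needs >= 2 patients with included slices")
    scores = np.array([s.score for s in data])
    labels = np.array([s.matched.truth_present for s in data])

    fold_thresholds: dict[str, float] = {}
    pred = np.zeros(len(data), dtype=bool)
    det_area = np.zeros(len(data))
    for train_idx, test_idx in LeaveOneGroupOut().split(scores, labels, groups=patients):
        held_out = patients[test_idx[0]]
        train_labels = labels[train_idx]
        if train_labels.all() or not train_labels.any():
            raise ValidationError(
                f"training fold for patient {held_out} is single-class; cannot optimize"
            )
        choice = youden_optimal(roc_from_scores(scores[train_idx], train_labels), grid_step)
        fold_thresholds[str(held_out)] = choice.threshold
        for i in test_idx:
            pred[i] = scores[i] > choice.threshold
            det_area[i] = data[i].area_at(choice.threshold)

    sens, spec, _ = confusion_metrics(pred, labels)
    truth_area = np.array([s.matched.truth_area_mm2 for s in data])
    r_all = pearson_r(det_area, truth_area) if len(data) >= 3 else float("nan")
    if labels.sum() >= 3:
        r_pos = pearson_r(det_area[labels], truth_area[labels])
    else:
        warnings.warn("too few positive slices for a positive-only correlation", stacklevel=2)
        r_pos = float("nan")
    return CvReport(
        reference_kind=data[0].ref_kind,
        subset=subset,
        fold_thresholds=fold_thresholds,
        pooled_sensitivity=sens,
        pooled_specificity=spec,
        pearson_r_all=r_all,
        pearson_r_positive=r_pos,
        n_slices=len(data),
        n_positive=int(labels.sum()),
    )
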