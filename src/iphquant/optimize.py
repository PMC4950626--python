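"""ROC analysis and Youden-optimal threshold selection.

Slice-level detection scores (max normalized intensity over the wall) are
swept against presence-by-histology labels. Candidate thresholds are the
midpoints between consecutive distinct scores plus one sentinel below the
minimum and one above the maximum; a prediction is positive when
``score > t`` (strict, matching "exceeded" in the detection rule). The
operating threshold is chosen on a 0.1-spaced lattice — the granularity at
which such thresholds are reported clinically — by maximizing Youden's
J = sensitivity + specificity - 1, breaking ties toward the larger threshold
(higher specificity, i.e. fewer false positives).

The same procedure is exposed as a scikit-learn estimator,
:class:`YoudenThresholdClassifier`, so it can sit inside sklearn model
selection (e.g. ``LeaveOneGroupOut`` over patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import ValidationError

__all__ = [
    "RocCurve",
    "ThresholdChoice",
    "roc_from_scores",
    "youden_optimal",
    "YoudenThresholdClassifier",
    "DEFAULT_GRID_STEP",
]

DEFAULT_GRID_STEP = 0.1


@dataclass
class RocCurve:
    """A full threshold sweep: (threshold, sensitivity, specificity) triples.

    Thresholds increase strictly; the first point is the degenerate
    (sens 1, spec 0) corner and the last is (sens 0, spec 1). The underlying
    scores and labels are retained so operating points can be re-evaluated at
    arbitrary thresholds (needed for lattice snapping).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_positive: int
    n_negative: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def operating_point(self, t: float) -> tuple[float, float]:
        """(sensitivity, specificity) of the rule ``score > t``."""
        pos = self.scores[self.labels]
        neg = self.scores[~self.labels]
        return float((pos > t).mean()), float((neg <= t).mean())


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    youden: float
    sensitivity: float
    specificity: float


def roc_from_scores(scores, labels) -> RocCurve:
    """Build the ROC curve of the rule ``score > t`` over all useful thresholds.

    AUC is the trapezoidal integral of sensitivity against false-positive
    rate, which with midpoint thresholds equals the tie-corrected
    concordant-pair (Mann–Whitney) fraction.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.shape != labels.shape or scores.size < 2:
        raise ValidationError("scores and labels must be equal-length with >= 2 items")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("labels must contain both classes")

    distinct = np.unique(scores)
    if distinct.size > 1:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        t_lo = 2 * distinct[0] - mids[0]
        t_hi = 2 * distinct[-1] - mids[-1]
        thresholds = np.concatenate(([t_lo], mids, [t_hi]))
    else:
        thresholds = np.array([distinct[0] - 1.0, distinct[0] + 1.0])

    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    sens = (n_pos - np.searchsorted(pos, thresholds, side="right")) / n_pos
    spec = np.searchsorted(neg, thresholds, side="right") / n_neg
    fpr = 1.0 - spec  # decreasing along increasing threshold
    auc = float(-np.trapezoid(sens, fpr))
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
        scores=scores,
        labels=labels,
    )


def youden_optimal(roc: RocCurve, grid_step: float = DEFAULT_GRID_STEP) -> ThresholdChoice:
    """Youden-optimal threshold on the multiple-of-``grid_step`` lattice.

    Each ROC candidate threshold is snapped to its nearest lattice value,
    duplicates are merged, and sensitivity/specificity are re-evaluated at
    the lattice threshold; ties in J are broken toward the larger threshold.
    """
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    lattice_idx = np.unique(np.round(roc.thresholds / grid_step).astype(np.int64))
    candidates = np.round(lattice_idx * grid_step, 12)

    best: ThresholdChoice | None = None
    for t in candidates:  # ascending, so >= implements the larger-threshold tie-break
        sens, spec = roc.operating_point(float(t))
        j = sens + spec - 1.0
        if best is None or j >= best.youden - 1e-12:
            best = ThresholdChoice(threshold=float(t), youden=j, sensitivity=sens, specificity=spec)
    assert best is not None
    return best


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-cutoff classifier fitted by Youden-index maximization.

    X is the (n,) or (n, 1) array of per-slice detection scores; y the boolean
    presence labels. ``fit`` runs the full ROC sweep and lattice search;
    ``predict`` applies the strict rule ``score > threshold_``.

    Attributes
    ----------
    threshold_ : float
        The selected cutoff on the grid_step lattice.
    youden_, sensitivity_, specificity_ : float
        Training operating point at ``threshold_``.
    roc_ : RocCurve
        The full training sweep (for diagnostics/plots).
    """

    def __init__(self, grid_step: float = DEFAULT_GRID_STEP):
        self.grid_step = grid_step

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValidationError("X must be a 1-D score vector or an (n, 1) column")
        return X

    def fit(self, X, y):
        scores = self._scores(X)
        y = np.asarray(y, dtype=bool).ravel()
        self.roc_ = roc_from_scores(scores, y)
        choice = youden_optimal(self.roc_, self.grid_step)
        self.threshold_ = choice.threshold
        self.youden_ = choice.youden
        self.sensitivity_ = choice.sensitivity
        self.specificity_ = choice.specificity
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        return self._scores(X) > self.threshold_
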