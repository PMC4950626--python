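import numpy as np
import pytest

import iphquant as iq


def make_slice(pixels, spacing=(1.0, 1.0), pid="P01", idx=0, pos=0.0) -> iq.ImageSlice:
    return iq.ImageSlice(
        patient_id=pid, slice_index=idx, position_mm=pos, pixels=np.asarray(pixels, float),
        spacing_mm=spacing,
    )


def square(x0, y0, x1, y1) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Scalar brute-force even-odd ray-casting test (independent oracle)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if y1 == y2:
            continue
        if (y1 > y) != (y2 > y) and x < (x2 - x1) * (y - y1) / (y2 - y1) + x1:
            inside = not inside
    return inside


def brute_polygon_mask(poly: np.ndarray, s: iq.ImageSlice) -> np.ndarray:
    nr, nc = s.pixels.shape
    sr, sc = s.spacing_mm
    out = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            out[r, c] = point_in_polygon(c * sc, r * sr, poly)
    return out


def brute_circle_mask(center, diameter, s: iq.ImageSlice) -> np.ndarray:
    nr, nc = s.pixels.shape
    sr, sc = s.spacing_mm
    out = np.zeros((nr, nc), dtype=bool)
    for r in range(nr):
        for c in range(nc):
            out[r, c] = (c * sc - center[0]) ** 2 + (r * sr - center[1]) ** 2 <= (diameter / 2) ** 2
    return out


def star_polygon(rng: np.random.Generator, center, r_lo=3.0, r_hi=25.0, n_max=12) -> np.ndarray:
    """Random star-shaped (hence simple) polygon around ``center``."""
    n = int(rng.integers(3, n_max + 1))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    if np.min(np.diff(angles, append=angles[0] + 2 * np.pi)) < 1e-3:
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False) + rng.uniform(0, 2 * np.pi)
    radii = rng.uniform(r_lo, r_hi, size=n)
    return np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )


def pair_count_auc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney concordance by exhaustive pair enumeration."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def matched_cohort(cohort: iq.Cohort) -> list[iq.MatchedSlice]:
    return iq.match_sections(list(zip(cohort.slices, cohort.annotations)), cohort.sections)


@pytest.fixture(scope="session")
def noiseless_cohort() -> iq.Cohort:
    """Small noiseless, uniform-coil, calcification-free phantom cohort."""
    cfg = iq.PhantomConfig(
        n_patients=6,
        slices_per_patient=6,
        image_size_px=(96, 96),
        noise_sigma_ratio=0.0,
        calcified_probability=0.0,
        seed=7,
    )
    return iq.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_matched(noiseless_cohort) -> list[iq.MatchedSlice]:
    return matched_cohort(noiseless_cohort)


def tiny_matched(present: bool, area: float, frac: float) -> iq.MatchedSlice:
    """A MatchedSlice with prescribed truth fields on a placeholder image."""
    s = make_slice(np.full((8, 8), 50.0))
    ann = iq.AnnotationSet(
        patient_id="P01", slice_index=0, lumen_center=(3.0, 3.0), outer_wall=square(0.5, 0.5, 6.5, 6.5)
    )
    return iq.MatchedSlice(
        slice=s, ann=ann, truth_present=present, truth_area_mm2=area,
        truth_calcified_fraction=frac, n_sections=1,
    )
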