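"""Synthetic vessel-wall MR phantom with known IPH ground truth.

Each slice emulates the tissue layout the detection method relies on: a
superficial SCM ellipse near the top edge (the skin side), a deep adjacent
muscle ellipse beside the artery, and a carotid cross-section — dark lumen,
isointense wall annulus — placed deep in the image. With configurable
probability an IPH disk is painted inside the annulus at a controlled
contrast ratio to muscle, optionally with a concentric hypointense
calcification sub-disk. The whole image is modulated by an exponential
coil-sensitivity field decaying with depth from the top edge, then Gaussian
noise is added and the result clipped at zero.

All geometry is circles/ellipses so painted truth areas have closed forms and
every painted mask doubles as an exact oracle for the detection stage. The
generated annotations and histology rows use the package's own on-disk
formats, so a phantom cohort is interface-identical to a real one.

Defaults mirror the clinical study's scale: 14 patients x ~10 slices, 47%
slice-level IPH prevalence, IPH at 1.6x muscle, ~22% of positive slices
heavily (>50%) calcified, 5% Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AnnotationSet,
    HistologySection,
    ImageSlice,
    ValidationError,
    write_annotations,
    write_histology,
    write_slice,
)

__all__ = ["PhantomConfig", "PhantomTruth", "Cohort", "generate_cohort", "write_cohort"]

# Vessel cross-section geometry (mm). The IPH disk orbits midway through the
# wall band, so its radius may not exceed half the band width.
LUMEN_RADIUS_MM = 2.0
WALL_RADIUS_MM = 5.0
OUTER_CONTOUR_RADIUS_MM = 6.0
IPH_ORBIT_MM = (LUMEN_RADIUS_MM + WALL_RADIUS_MM) / 2.0

BACKGROUND_RATIO = 0.2
LUMEN_RATIO = 0.1


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters of the synthetic cohort (the stated world)."""

    n_patients: int = 14
    slices_per_patient: int = 10
    image_size_px: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (0.31, 0.31)
    muscle_signal: float = 100.0
    wall_signal_ratio: float = 1.0
    iph_contrast_ratio: float = 1.6
    iph_prevalence: float = 0.47
    iph_radius_range_mm: tuple[float, float] = (0.5, 1.4)
    calcified_probability: float = 0.45
    calcified_fraction_range: tuple[float, float] = (0.1, 0.9)
    calcification_signal_ratio: float = 0.3
    coil_decay_mm: float = math.inf
    noise_sigma_ratio: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.slices_per_patient < 1:
            raise ValidationError("n_patients and slices_per_patient must be >= 1")
        if min(self.image_size_px) < 8 or min(self.spacing_mm) <= 0:
            raise ValidationError("image_size_px must be >= 8 px with positive spacing")
        if self.muscle_signal <= 0 or self.wall_signal_ratio <= 0 or self.iph_contrast_ratio <= 0:
            raise ValidationError("signal levels and ratios must be positive")
        if not 0 <= self.iph_prevalence <= 1 or not 0 <= self.calcified_probability <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        lo, hi = self.iph_radius_range_mm
        if not 0 < lo <= hi:
            raise ValidationError("iph_radius_range_mm must satisfy 0 < lo <= hi")
        band = (WALL_RADIUS_MM - LUMEN_RADIUS_MM) / 2.0
        if hi > band:
            raise ValidationError(
                f"IPH radius up to {hi} mm does not fit the {band} mm half-width of the wall band"
            )
        flo, fhi = self.calcified_fraction_range
        if not 0 <= flo <= fhi <= 1:
            raise ValidationError("calcified_fraction_range must be ordered within [0, 1]")
        if not self.calcification_signal_ratio < self.iph_contrast_ratio:
            raise ValidationError("calcification must be hypointense relative to IPH")
        if self.coil_decay_mm <= 0:
            raise ValidationError("coil_decay_mm must be positive (use inf for a uniform coil)")
        if self.noise_sigma_ratio < 0:
            raise ValidationError("noise_sigma_ratio must be >= 0")
        w = (self.image_size_px[1] - 1) * self.spacing_mm[1]
        h = (self.image_size_px[0] - 1) * self.spacing_mm[0]
        if w < 26 or h < 17:
            raise ValidationError(
                f"image extent {w:.1f} x {h:.1f} mm too small for the fixed tissue layout"
            )


@dataclass
class PhantomTruth:
    """Painted ground truth for one slice (stands in for histology)."""

    iph_mask: np.ndarray
    iph_area_mm2: float
    calcified_fraction: float
    contrast_ratio_used: float


@dataclass
class Cohort:
    slices: list[ImageSlice]
    annotations: list[AnnotationSet]
    sections: list[HistologySection]
    truths: list[PhantomTruth]


def _regular_polygon(center: tuple[float, float], radius: float, n: int = 48) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


def _ellipse_polygon(center: tuple[float, float], a: float, b: float, n: int = 64) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + a * np.cos(th), center[1] + b * np.sin(th)])


@dataclass(frozen=True)
class _Layout:
    """Tissue placement in mm, derived from the image extent."""

    lumen_center: tuple[float, float]
    scm_center: tuple[float, float]
    scm_axes: tuple[float, float]
    adj_center: tuple[float, float]
    adj_axes: tuple[float, float]


def _layout(config: PhantomConfig) -> _Layout:
    h = (config.image_size_px[0] - 1) * config.spacing_mm[0]
    w = (config.image_size_px[1] - 1) * config.spacing_mm[1]
    lay = _Layout(
        lumen_center=(0.5 * w, 0.6 * h),
        scm_center=(0.5 * w, 0.15 * h),
        scm_axes=(0.2 * w, 0.09 * h),
        adj_center=(0.8 * w, 0.62 * h),
        adj_axes=(0.07 * w, 0.08 * h),
    )
    # The reference ellipses must stay clear of the detection contour.
    for cx, cy, ax in (
        (*lay.scm_center, lay.scm_axes[1]),
        (*lay.adj_center, lay.adj_axes[0]),
    ):
        d = math.hypot(cx - lay.lumen_center[0], cy - lay.lumen_center[1])
        if d - ax <= OUTER_CONTOUR_RADIUS_MM:
            raise ValidationError("image too small: reference region overlaps the vessel contour")
    return lay


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Generate the full synthetic cohort; one named RNG stream per patient."""
    lay = _layout(config)
    nr, nc = config.image_size_px
    sr, sc = config.spacing_mm
    ys = np.arange(nr) * sr
    xs = np.arange(nc) * sc
    X, Y = np.meshgrid(xs, ys)
    mu = config.muscle_signal

    def disk(center, radius):
        return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius * radius

    def ellipse(center, a, b):
        return ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 <= 1.0

    scm_mask = ellipse(lay.scm_center, *lay.scm_axes)
    adj_mask = ellipse(lay.adj_center, *lay.adj_axes)
    wall_mask = disk(lay.lumen_center, WALL_RADIUS_MM) & ~disk(lay.lumen_center, LUMEN_RADIUS_MM)
    lumen_mask = disk(lay.lumen_center, LUMEN_RADIUS_MM)
    coil = np.exp(-Y / config.coil_decay_mm) if math.isfinite(config.coil_decay_mm) else 1.0

    ann_template = dict(
        lumen_center=lay.lumen_center,
        outer_wall=_regular_polygon(lay.lumen_center, OUTER_CONTOUR_RADIUS_MM),
        scm=_ellipse_polygon(lay.scm_center, *lay.scm_axes),
        adjacent_muscle=_ellipse_polygon(lay.adj_center, *lay.adj_axes),
    )

    cohort = Cohort([], [], [], [])
    for p in range(config.n_patients):
        rng = np.random.default_rng([config.seed, p])
        pid = f"P{p + 1:02d}"
        for j in range(config.slices_per_patient):
            position = float(j - config.slices_per_patient // 2)
            base = np.full((nr, nc), BACKGROUND_RATIO * mu)
            base[scm_mask] = mu
            base[adj_mask] = mu
            base[wall_mask] = config.wall_signal_ratio * mu
            base[lumen_mask] = LUMEN_RATIO * mu

            iph_mask = np.zeros((nr, nc), dtype=bool)
            calc_frac = 0.0
            if rng.random() < config.iph_prevalence:
                radius = rng.uniform(*config.iph_radius_range_mm)
                angle = rng.uniform(0.0, 2 * np.pi)
                center = (
                    lay.lumen_center[0] + IPH_ORBIT_MM * np.cos(angle),
                    lay.lumen_center[1] + IPH_ORBIT_MM * np.sin(angle),
                )
                iph_mask = disk(center, radius)
                base[iph_mask] = config.iph_contrast_ratio * mu
                if iph_mask.any() and rng.random() < config.calcified_probability:
                    frac = rng.uniform(*config.calcified_fraction_range)
                    calc_mask = iph_mask & disk(center, radius * math.sqrt(frac))
                    base[calc_mask] = config.calcification_signal_ratio * mu
                    calc_frac = float(calc_mask.sum()) / float(iph_mask.sum())

            pixels = base * coil
            if config.noise_sigma_ratio > 0:
                pixels = pixels + rng.normal(0.0, config.noise_sigma_ratio * mu, size=(nr, nc))
            pixels = np.clip(pixels, 0.0, None)

            area = float(iph_mask.sum()) * sr * sc
            present = bool(iph_mask.any())
            cohort.slices.append(
                ImageSlice(
                    patient_id=pid,
                    slice_index=j,
                    position_mm=position,
                    pixels=pixels,
                    spacing_mm=(sr, sc),
                )
            )
            cohort.annotations.append(AnnotationSet(patient_id=pid, slice_index=j, **ann_template))
            cohort.sections.append(
                HistologySection(
                    patient_id=pid,
                    position_mm=position,
                    iph_present=present,
                    iph_area_mm2=area if present else 0.0,
                    calcified_fraction=calc_frac if present else 0.0,
                )
            )
            cohort.truths.append(
                PhantomTruth(
                    iph_mask=iph_mask,
                    iph_area_mm2=area,
                    calcified_fraction=calc_frac,
                    contrast_ratio_used=config.iph_contrast_ratio,
                )
            )
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the package's standard on-disk formats."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for s in cohort.slices:
        write_slice(s, outdir / "images" / f"{s.patient_id}_{s.slice_index:03d}.nii")
    write_annotations(cohort.annotations, outdir / "annotations.json")
    write_histology(cohort.sections, outdir / "histology.csv")
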