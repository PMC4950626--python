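"""Readers and writers for image slices, contour annotations and histology tables.

On-disk formats are deliberately boring and diffable: NIfTI (preferred) or
16-bit grayscale TIFF for images, each with a JSON sidecar carrying patient
metadata; a versioned JSON document for per-slice contour sets; RFC-4180 CSV
for histology ground truth. Image coordinates are millimetres with the origin
at the centre of pixel (0, 0), x running along columns and y along rows, so
polygon geometry stays exact at any pixel spacing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, Polygon

__all__ = [
    "ImageSlice",
    "AnnotationSet",
    "HistologySection",
    "ValidationError",
    "MetadataError",
    "read_slice",
    "write_slice",
    "read_annotations",
    "write_annotations",
    "read_histology",
    "write_histology",
]

ANNOTATION_SCHEMA = "iphquant-annotations/1"


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class MetadataError(ValueError):
    """Required image metadata (e.g. pixel spacing) is missing."""


def _validate_polygon(vertices: np.ndarray, role: str, where: str) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError(
            f"{where}: polygon '{role}' needs >= 3 [x, y] vertices, got shape {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{where}: polygon '{role}' has non-finite vertices")
    poly = Polygon(v)
    if poly.area == 0:
        raise ValidationError(f"{where}: polygon '{role}' is degenerate (zero area)")
    if not poly.is_simple or not poly.is_valid:
        raise ValidationError(f"{where}: polygon '{role}' is self-intersecting")
    return v


@dataclass
class ImageSlice:
    """One axial grayscale MR slice — the unit of IPH detection.

    ``position_mm`` is the signed longitudinal distance from the carotid
    bifurcation (distal positive); it is the key used to match the slice to
    histology sections. Intensities are arbitrary scanner units, stored
    unscaled.
    """

    patient_id: str
    slice_index: int
    position_mm: float
    pixels: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.spacing_mm = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        where = f"slice {self.patient_id}/{self.slice_index}"
        if self.slice_index < 0:
            raise ValidationError(f"{where}: slice_index must be >= 0")
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValidationError(f"{where}: pixels must be 2-D with >= 2 rows and columns")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValidationError(f"{where}: intensities must be finite and >= 0")
        if min(self.spacing_mm) <= 0:
            raise ValidationError(f"{where}: pixel spacing must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]


@dataclass
class AnnotationSet:
    """Reviewer-drawn contours for one slice, in mm image coordinates.

    ``outer_wall`` is the loose boundary confining IPH detection. ``scm``
    (sternocleidomastoid) and ``adjacent_muscle`` are the manual reference
    regions; either may be absent (an absent SCM models slices where the
    muscle lies outside the 4 cm reference ROI).
    """

    patient_id: str
    slice_index: int
    lumen_center: tuple[float, float]
    outer_wall: np.ndarray
    scm: np.ndarray | None = None
    adjacent_muscle: np.ndarray | None = None

    def __post_init__(self) -> None:
        where = f"annotations {self.patient_id}/{self.slice_index}"
        self.lumen_center = (float(self.lumen_center[0]), float(self.lumen_center[1]))
        self.outer_wall = _validate_polygon(self.outer_wall, "outer_wall", where)
        if self.scm is not None:
            self.scm = _validate_polygon(self.scm, "scm", where)
        if self.adjacent_muscle is not None:
            self.adjacent_muscle = _validate_polygon(self.adjacent_muscle, "adjacent_muscle", where)
        if not Polygon(self.outer_wall).contains(Point(self.lumen_center)):
            raise ValidationError(f"{where}: lumen_center must lie inside outer_wall")


@dataclass
class HistologySection:
    """Ground truth for one histology section: IPH presence, area, calcification."""

    patient_id: str
    position_mm: float
    iph_present: bool
    iph_area_mm2: float
    calcified_fraction: float

    def __post_init__(self) -> None:
        where = f"histology {self.patient_id}@{self.position_mm}mm"
        self.iph_present = bool(self.iph_present)
        self.iph_area_mm2 = float(self.iph_area_mm2)
        self.calcified_fraction = float(self.calcified_fraction)
        if self.iph_area_mm2 < 0:
            raise ValidationError(f"{where}: iph_area_mm2 must be >= 0")
        if not 0.0 <= self.calcified_fraction <= 1.0:
            raise ValidationError(f"{where}: calcified_fraction must lie in [0, 1]")
        if not self.iph_present and (self.iph_area_mm2 != 0 or self.calcified_fraction != 0):
            raise ValidationError(
                f"{where}: IPH-absent section must have zero area and zero calcified fraction"
            )


# ---------------------------------------------------------------------------
# images


def _default_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _tiff_spacing(page: "tifffile.TiffPage") -> tuple[float, float] | None:
    """Pixel spacing (row, col) in mm from TIFF resolution tags, if present."""
    tags = page.tags
    if "XResolution" not in tags or "YResolution" not in tags:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 1
    unit = int(unit)
    if unit == 2:  # inch
        unit_mm = 25.4
    elif unit == 3:  # centimetre
        unit_mm = 10.0
    else:
        return None

    def _ratio(tag) -> float:
        v = tag.value
        return v[0] / v[1] if isinstance(v, tuple) else float(v)

    xres = _ratio(tags["XResolution"])  # pixels per unit along columns
    yres = _ratio(tags["YResolution"])  # pixels per unit along rows
    if xres <= 0 or yres <= 0:
        return None
    return (unit_mm / yres, unit_mm / xres)


def read_slice(path: str | Path, sidecar: str | Path | None = None) -> ImageSlice:
    """Read a NIfTI or 16-bit TIFF slice plus its JSON metadata sidecar.

    Spacing is taken from the sidecar's ``spacing_mm`` when present, falling
    back to the NIfTI header zooms or the TIFF resolution tags; absence from
    both is a :class:`MetadataError`.
    """
    path = Path(path)
    sidecar = _default_sidecar(path) if sidecar is None else Path(sidecar)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if not sidecar.exists():
        raise IOError(f"sidecar file not found: {sidecar}")
    meta = json.loads(sidecar.read_text())

    header_spacing: tuple[float, float] | None = None
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        pixels = np.asarray(img.dataobj, dtype=float)
        pixels = np.squeeze(pixels)
        zooms = img.header.get_zooms()[:2]
        if zooms[0] > 0 and zooms[1] > 0:
            header_spacing = (float(zooms[0]), float(zooms[1]))
    elif name.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            pixels = page.asarray().astype(float)
            header_spacing = _tiff_spacing(page)
    else:
        raise IOError(f"unsupported image format: {path}")

    spacing = meta.get("spacing_mm")
    if spacing is not None:
        spacing = (float(spacing[0]), float(spacing[1]))
    elif header_spacing is not None:
        spacing = header_spacing
    else:
        raise MetadataError(f"{path}: pixel spacing absent from both header and sidecar")

    return ImageSlice(
        patient_id=str(meta["patient_id"]),
        slice_index=int(meta["slice_index"]),
        position_mm=float(meta["position_mm"]),
        pixels=pixels,
        spacing_mm=spacing,
    )


def write_slice(s: ImageSlice, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a slice as NIfTI (float, exact) or 16-bit TIFF, plus JSON sidecar."""
    path = Path(path)
    sidecar = _default_sidecar(path) if sidecar is None else Path(sidecar)
    sr, sc = s.spacing_mm
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag([sr, sc, 1.0, 1.0])
        img = nib.Nifti1Image(s.pixels.astype(np.float64), affine)
        img.header.set_zooms((sr, sc))
        nib.save(img, str(path))
    elif name.endswith((".tif", ".tiff")):
        data = s.pixels
        if np.any(data > np.iinfo(np.uint16).max) or np.any(np.mod(data, 1) != 0):
            raise ValidationError(
                f"{path}: 16-bit TIFF requires integral intensities in [0, 65535]; use NIfTI"
            )
        tifffile.imwrite(
            str(path),
            data.astype(np.uint16),
            resolution=(10.0 / sc, 10.0 / sr),
            resolutionunit="CENTIMETER",
        )
    else:
        raise IOError(f"unsupported image format: {path}")
    sidecar.write_text(
        json.dumps(
            {
                "patient_id": s.patient_id,
                "slice_index": s.slice_index,
                "position_mm": s.position_mm,
                "spacing_mm": [sr, sc],
            },
            indent=2,
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[AnnotationSet]:
    """Read the versioned JSON contour document into validated AnnotationSets."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("schema") != ANNOTATION_SCHEMA:
        warnings.warn(
            f"{path}: unknown annotation schema {doc.get('schema')!r}; "
            f"expected {ANNOTATION_SCHEMA!r}",
            stacklevel=2,
        )
    out = []
    for rec in doc["slices"]:
        out.append(
            AnnotationSet(
                patient_id=str(rec["patient_id"]),
                slice_index=int(rec["slice_index"]),
                lumen_center=tuple(rec["lumen_center"]),
                outer_wall=np.asarray(rec["outer_wall"], dtype=float),
                scm=np.asarray(rec["scm"], dtype=float) if rec.get("scm") is not None else None,
                adjacent_muscle=(
                    np.asarray(rec["adjacent_muscle"], dtype=float)
                    if rec.get("adjacent_muscle") is not None
                    else None
                ),
            )
        )
    return out


def write_annotations(annotations: list[AnnotationSet], path: str | Path) -> None:
    recs = []
    for a in annotations:
        recs.append(
            {
                "patient_id": a.patient_id,
                "slice_index": a.slice_index,
                "lumen_center": list(a.lumen_center),
                "outer_wall": a.outer_wall.tolist(),
                "scm": a.scm.tolist() if a.scm is not None else None,
                "adjacent_muscle": (
                    a.adjacent_muscle.tolist() if a.adjacent_muscle is not None else None
                ),
            }
        )
    Path(path).write_text(json.dumps({"schema": ANNOTATION_SCHEMA, "slices": recs}, indent=2) + "\n")


# ---------------------------------------------------------------------------
# histology

_HISTOLOGY_COLUMNS = ["patient_id", "position_mm", "iph_present", "iph_area_mm2", "calcified_fraction"]


def read_histology(path: str | Path) -> list[HistologySection]:
    """Read the histology ground-truth CSV; every row is validated."""
    df = pd.read_csv(path)
    missing = [c for c in _HISTOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing histology columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                HistologySection(
                    patient_id=str(row.patient_id),
                    position_mm=float(row.position_mm),
                    iph_present=bool(int(row.iph_present)),
                    iph_area_mm2=float(row.iph_area_mm2),
                    calcified_fraction=float(row.calcified_fraction),
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path} row {i + 2}: {err}") from err
    return out


def write_histology(sections: list[HistologySection], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in sections],
            "position_mm": [s.position_mm for s in sections],
            "iph_present": [int(s.iph_present) for s in sections],
            "iph_area_mm2": [s.iph_area_mm2 for s in sections],
            "calcified_fraction": [s.calcified_fraction for s in sections],
        }
    )
    df.to_csv(path, index=False)
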