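"""Reading CT series and mask stacks, and writing result tables.

A CT series supplies the geometry that volumetry depends on: the physical
pixel spacing (mm), the axial position of every slice (mm along the patient
z axis), and the rescale parameters that map stored pixel values to
Hounsfield units.  Segmentation masks arrive either as a directory of
per-slice 2-D images (lexicographic filename order = slice order) or as a
single 3-D NIfTI volume.

All internal lengths are mm, areas mm2, volumes mm3; conversion to cc
(1 cc = 1000 mm3) happens only at reporting time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ocuvol")

#: 1 cc = 1 cm3 = 1000 mm3; clinical volume reports use cc.
MM3_PER_CC = 1000.0

#: Decimal places used when reporting volumes in cc.
CC_DECIMALS = 3

_MASK_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def mm3_to_cc(value_mm3: float) -> float:
    """Convert mm3 to cc, rounded to reporting precision (3 decimals)."""
    return round(value_mm3 / MM3_PER_CC, CC_DECIMALS)


@dataclass(frozen=True)
class CTSlice:
    """One axial CT slice with the metadata volumetry needs.

    ``pixel_array`` holds raw stored values; HU = raw * rescale_slope +
    rescale_intercept.  ``slice_position`` is mm along patient z.
    """

    pixel_array: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing: tuple[float, float]  # (row_mm, col_mm)
    slice_position: float
    instance_index: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixel_array)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixel_array must be a non-empty 2-D raster")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical pixel size and ordered inter-slice gaps.

    Parameters
    ----------
    p_w, p_h : float
        Pixel width / height in mm.
    gaps : tuple of float
        Distance h_i between slice i and i+1 in mm; length N-1 for N slices.
    """

    p_w: float
    p_h: float
    gaps: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.p_w <= 0 or self.p_h <= 0:
            raise ValueError("pixel dimensions must be strictly positive")
        if any(h <= 0 for h in self.gaps):
            raise ValueError("all inter-slice gaps must be strictly positive")
        object.__setattr__(self, "gaps", tuple(float(h) for h in self.gaps))

    @property
    def n_slices(self) -> int:
        return len(self.gaps) + 1

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel, mm2."""
        return self.p_w * self.p_h

    def z_positions(self, z0: float = 0.0) -> np.ndarray:
        """Axial position of each slice, mm, starting at ``z0``."""
        return z0 + np.concatenate([[0.0], np.cumsum(self.gaps)])

    @classmethod
    def uniform(cls, p_w: float, p_h: float, gap: float, n_slices: int) -> "VoxelGeometry":
        if n_slices < 2:
            raise ValueError("need at least 2 slices")
        return cls(p_w=p_w, p_h=p_h, gaps=(gap,) * (n_slices - 1))


# ---------------------------------------------------------------------------
# DICOM series input
# ---------------------------------------------------------------------------

def _slice_z(ds) -> float | None:
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        return float(ipp[2])
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    return None


def read_ct_series(path: str | Path) -> tuple[list[CTSlice], VoxelGeometry]:
    """Read a directory of single-frame CT DICOM files as an ordered series.

    Slices are sorted by ascending axial position; inter-slice gaps are the
    successive position differences (the physically correct h_i even when
    the series is non-contiguous).  Pixel spacing must be present and
    uniform across the series.  If positions are missing everywhere the
    declared SliceThickness is used as a uniform gap, with a warning.
    """
    import pydicom

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # non-DICOM clutter (sidecars etc.)
        if getattr(ds, "PixelData", None) is not None:
            datasets.append((p, ds))
    if len(datasets) < 2:
        raise ValueError(f"need at least 2 DICOM slices in {path}, found {len(datasets)}")

    spacings = []
    for p, ds in datasets:
        sp = getattr(ds, "PixelSpacing", None)
        if sp is None:
            raise ValueError(f"missing PixelSpacing metadata in {p.name}")
        spacings.append((p.name, (float(sp[0]), float(sp[1]))))
    ref = spacings[0][1]
    offenders = [name for name, sp in spacings if not np.allclose(sp, ref, atol=1e-9)]
    if offenders:
        raise ValueError(f"non-uniform pixel spacing across series; offending slices: {offenders}")

    zs = [_slice_z(ds) for _, ds in datasets]
    if all(z is not None for z in zs):
        if len(set(np.round(zs, 9))) != len(zs):
            raise ValueError(f"duplicate slice positions {sorted(zs)}: ambiguous ordering")
        order = np.argsort(zs)
        datasets = [datasets[i] for i in order]
        zs = [zs[i] for i in order]
        gaps = tuple(float(b - a) for a, b in zip(zs, zs[1:]))
    else:
        thickness = getattr(datasets[0][1], "SliceThickness", None)
        if thickness is None:
            raise ValueError("no slice positions and no SliceThickness to fall back on")
        logger.warning(
            "slice positions missing; falling back to declared SliceThickness=%s mm "
            "as a uniform gap (instance-number order)", thickness,
        )
        datasets.sort(key=lambda t: int(getattr(t[1], "InstanceNumber", 0)))
        zs = [float(thickness) * i for i in range(len(datasets))]
        gaps = (float(thickness),) * (len(datasets) - 1)

    slices = []
    for idx, ((_, ds), z) in enumerate(zip(datasets, zs)):
        slices.append(
            CTSlice(
                pixel_array=ds.pixel_array,
                rescale_slope=float(getattr(ds, "RescaleSlope", 1.0)),
                rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
                pixel_spacing=(ref[0], ref[1]),
                slice_position=float(z),
                instance_index=idx,
            )
        )
    # PixelSpacing is (row spacing, column spacing) = (p_h, p_w)
    geometry = VoxelGeometry(p_w=ref[1], p_h=ref[0], gaps=gaps)
    return slices, geometry


def hu_from_raw(ct_slice: CTSlice) -> np.ndarray:
    """Stored values -> Hounsfield units via the DICOM rescale transform."""
    return (
        np.asarray(ct_slice.pixel_array, dtype=np.float64) * ct_slice.rescale_slope
        + ct_slice.rescale_intercept
    )


# ---------------------------------------------------------------------------
# Mask stacks
# ---------------------------------------------------------------------------

def read_mask_stack(
    path: str | Path,
    geometry: VoxelGeometry | None = None,
) -> np.ndarray:
    """Read a binary mask volume as a (slices, rows, cols) uint8 array.

    ``path`` is either a directory of per-slice PNG/TIFF images (lexicographic
    filename order = slice order) or a single NIfTI file.  Values are coerced
    to {0,1} with the half-of-dtype-maximum rule of
    :func:`ocuvol.mask_processing.binarize`.
    """
    from .mask_processing import binarize

    path = Path(path)
    if path.is_dir():
        from PIL import Image

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _MASK_IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no mask images (*.png, *.tif) found in {path}")
        rasters = [np.asarray(Image.open(p)) for p in files]
        shapes = {r.shape for r in rasters}
        if len(shapes) != 1:
            raise ValueError(f"mask slices have mismatched dimensions: {sorted(shapes)}")
        volume = np.stack([binarize(r) for r in rasters])
    else:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D mask volume, got shape {data.shape}")
        # NIfTI stores (x, y, z); slices-first here.
        volume = np.stack([binarize(data[:, :, k]) for k in range(data.shape[2])])

    if geometry is not None and volume.shape[0] != geometry.n_slices:
        raise ValueError(
            f"mask stack has {volume.shape[0]} slices but geometry declares "
            f"{geometry.n_slices} ({len(geometry.gaps)} gaps)"
        )
    return volume.astype(np.uint8)


def write_mask_stack(volume: np.ndarray, path: str | Path, dialect: str = "slices") -> None:
    """Write a binary volume as per-slice PNGs (``slices``) or NIfTI (``volume``).

    Foreground is written as 255 in PNG so the images are viewable; the
    round trip through :func:`read_mask_stack` restores exact {0,1} values.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("mask volume must be 3-D (slices, rows, cols)")
    path = Path(path)
    if dialect == "slices":
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        width = len(str(volume.shape[0] - 1))
        for k, sl in enumerate(volume):
            img = Image.fromarray((sl > 0).astype(np.uint8) * 255)
            img.save(path / f"slice_{k:0{width}d}.png")
    elif dialect == "volume":
        import nibabel as nib

        data = np.moveaxis((volume > 0).astype(np.uint8), 0, 2)
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown mask dialect {dialect!r} (use 'slices' or 'volume')")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["subject_id", "eye", "slice_index", "z_mm", "pixel_count", "area_mm2", "radius_mm"]
VOLUME_COLUMNS = ["subject_id", "eye", "method", "cap_mode", "mid_volume_cc", "cap_volume_cc", "total_cc"]


def measurements_table(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=MEASUREMENT_COLUMNS)


def volumes_table(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=VOLUME_COLUMNS)
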