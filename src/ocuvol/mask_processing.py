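"""From raw mask volumes to per-eye, per-slice physical measurements.

The chain is: binarize the raster, split the volume into per-eye stacks by
3-D connected components, optionally crop to a region of interest, then
measure every slice: foreground pixel count A, physical area
S = A * p_h * p_w (mm2), and the equivalent radius r = sqrt(S / pi) of the
circle with the same area.  The circle approximation is the basis of the
downstream stacking formulas and is reasonable for near-circular axial
cross-sections of the eyeball.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dicom_io import VoxelGeometry

logger = logging.getLogger("ocuvol")


def binarize(raster: np.ndarray) -> np.ndarray:
    """Threshold a grayscale raster to {0,1} (uint8).

    The threshold is half the maximum representable value of the raster's
    dtype (e.g. 127.5 for uint8), which keeps exact binary exports intact
    and is robust to anti-aliased mask images.  Float rasters are assumed
    to live in [0,1] and use threshold 0.5; boolean input passes through.
    """
    arr = np.asarray(raster)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        if arr.size and arr.max() <= 1 and arr.min() >= 0:
            return arr.astype(np.uint8)  # already binary: idempotent
        threshold = np.iinfo(arr.dtype).max / 2.0
    else:
        threshold = 0.5
    return (arr > threshold).astype(np.uint8)


@dataclass(frozen=True)
class MaskStack:
    """Ordered per-slice binary masks for one eye — the unit of volumetry.

    ``slices`` is a (N, rows, cols) array with values in {0,1}; ``geometry``
    carries the pixel size and the N-1 inter-slice gaps.
    """

    slices: np.ndarray
    geometry: VoxelGeometry
    laterality: str = "unknown"  # left | right | unknown
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim != 3:
            raise ValueError("slices must be 3-D (n_slices, rows, cols)")
        if arr.shape[0] < 2:
            raise ValueError("a mask stack needs at least 2 slices")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be in {0,1}; binarize first")
        if arr.shape[0] != self.geometry.n_slices:
            raise ValueError(
                f"{arr.shape[0]} slices but geometry declares {self.geometry.n_slices}"
            )
        if self.laterality not in ("left", "right", "unknown"):
            raise ValueError(f"bad laterality {self.laterality!r}")
        object.__setattr__(self, "slices", np.ascontiguousarray(arr, dtype=np.uint8))

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass(frozen=True)
class SliceMeasurement:
    """Per-slice morphometry: pixel count A, area S (mm2), radius r (mm)."""

    index: int
    pixel_count: int
    area: float
    radius: float
    z: float


def split_eyes(
    volume: np.ndarray,
    geometry: VoxelGeometry,
    subject_id: str = "",
    min_component_fraction: float = 0.01,
) -> list[MaskStack]:
    """Separate a binary volume into up to two per-eye mask stacks.

    3-D connected components (26-connectivity) are ranked by voxel count;
    the two largest are kept and components below ``min_component_fraction``
    of the largest are discarded as segmentation noise.  Laterality is
    assigned from the component centroid column relative to the image
    vertical midline (smaller column index = image-left).  Note that
    radiological left/right additionally depends on patient orientation;
    the caller may flip assignments from orientation metadata.
    """
    volume = binarize(np.asarray(volume)) if volume.dtype != np.uint8 else np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D binary volume")
    labels, n = ndimage.label(volume, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no foreground components found in mask volume")
    counts = np.bincount(labels.ravel())[1:]  # skip background
    order = np.argsort(counts)[::-1]
    keep = [int(i) + 1 for i in order[:2] if counts[i] >= min_component_fraction * counts[order[0]]]
    if n > len(keep):
        logger.debug("discarded %d small component(s) below the %.0f%% size rule",
                     n - len(keep), 100 * min_component_fraction)

    midline = volume.shape[2] / 2.0
    stacks: list[tuple[float, MaskStack]] = []
    centroids = ndimage.center_of_mass(volume, labels, keep)
    for lab, com in zip(keep, centroids):
        col = com[2]
        if len(keep) == 2:
            laterality = "left" if col < midline else "right"
        else:
            laterality = "unknown"
        stacks.append(
            (col, MaskStack(slices=(labels == lab).astype(np.uint8), geometry=geometry,
                            laterality=laterality, subject_id=subject_id))
        )
    if len(stacks) == 2 and stacks[0][1].laterality == stacks[1][1].laterality:
        # centroids on the same side of the midline: fall back to relative order
        stacks.sort(key=lambda t: t[0])
        stacks = [
            (stacks[0][0], MaskStack(stacks[0][1].slices, geometry, "left", subject_id)),
            (stacks[1][0], MaskStack(stacks[1][1].slices, geometry, "right", subject_id)),
        ]
    stacks.sort(key=lambda t: t[0])
    return [s for _, s in stacks]


def crop_roi(stack: MaskStack, margin_px: int = 2) -> MaskStack:
    """Crop to the tight row/column bounding box over all slices, plus margin.

    Cropping never changes pixel counts, so every measurement is identical
    before and after; it only shrinks the rasters to the region of interest.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    fg = stack.slices.any(axis=0)
    if not fg.any():
        return stack
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0 = max(rows[0] - margin_px, 0)
    r1 = min(rows[-1] + margin_px + 1, fg.shape[0])
    c0 = max(cols[0] - margin_px, 0)
    c1 = min(cols[-1] + margin_px + 1, fg.shape[1])
    return MaskStack(
        slices=stack.slices[:, r0:r1, c0:c1],
        geometry=stack.geometry,
        laterality=stack.laterality,
        subject_id=stack.subject_id,
    )


def radius_from_area(area_mm2: float) -> float:
    """Equivalent radius r = sqrt(S / pi) of the circle with area S."""
    if area_mm2 < 0:
        raise ValueError("area must be non-negative")
    return math.sqrt(area_mm2 / math.pi)


def measure_slices(stack: MaskStack, z0: float = 0.0) -> list[SliceMeasurement]:
    """Measure every slice: A (pixels), S = A*p_w*p_h (mm2), r = sqrt(S/pi) (mm).

    Empty slices yield zero count, area and radius.
    """
    geom = stack.geometry
    zs = geom.z_positions(z0)
    out = []
    for idx, sl in enumerate(stack.slices):
        count = int(sl.sum())
        area = count * geom.pixel_area
        out.append(
            SliceMeasurement(
                index=idx,
                pixel_count=count,
                area=area,
                radius=radius_from_area(area),
                z=float(zs[idx]),
            )
        )
    return out
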