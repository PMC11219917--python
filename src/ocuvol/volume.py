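"""The three volumetry methods and the spherical-cap end correction.

Given the equivalent-radius profile r_1..r_N of a slice stack with gaps
h_1..h_{N-1}, the stack's mid-section volume can be estimated by

* ``pixel_count``  — raw slice areas times the following gap,
  V = sum_i S_i * h_i (no circle approximation);
* ``cylinder``     — truncated-cylinder stacking, V_i = pi * r_i^2 * h_i,
  using the lower-index slice's radius per slab;
* ``cone``         — truncated-cone (frustum) stacking,
  V_i = (pi * h_i / 3) * (r_i^2 + r_i * r_{i+1} + r_{i+1}^2),
  which follows the curvature of a near-spherical body.

Because small terminal slices are excluded from segmentation, all three
under-cover the poles of the globe.  The cone method is therefore paired
with a spherical-cap correction: treating the globe as a sphere of radius
m (the largest equivalent radius in the profile), the volume beyond a
cutting plane at axial coordinate x1 is the solid-of-revolution integral

    V_cap = pi * Integral_{x1}^{m} (m^2 - x^2) dx
          = pi * (2 m^3 / 3 - m^2 x1 + x1^3 / 3).

In ``geometric`` mode each end gets its own cap, cut exactly at the
terminal included slice: x1 = sqrt(m^2 - r_end^2).  In ``literal`` mode
both caps share x1 = the smallest radius in the profile, treating that
radius directly as the integration bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .mask_processing import MaskStack, SliceMeasurement, crop_roi, measure_slices
from .preprocess import DEFAULT_MIN_RADIUS_FRACTION, SliceSelection, select_slices

logger = logging.getLogger("ocuvol")

METHODS = ("pixel_count", "cylinder", "cone")
CAP_MODES = ("none", "literal", "geometric")


@dataclass(frozen=True)
class RadiusProfile:
    """Equivalent radii r_i (mm), slice areas S_i (mm2) and gaps h_i (mm)."""

    radii: tuple[float, ...]
    gaps: tuple[float, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.radii)
        if len(self.areas) != n:
            raise ValueError("areas and radii must have equal length")
        if len(self.gaps) != n - 1:
            raise ValueError(f"need {n - 1} gaps for {n} radii, got {len(self.gaps)}")
        if any(r < 0 for r in self.radii):
            raise ValueError("radii must be non-negative")
        if any(h <= 0 for h in self.gaps):
            raise ValueError("gaps must be strictly positive")

    @property
    def n_slices(self) -> int:
        return len(self.radii)

    @classmethod
    def from_measurements(
        cls,
        measurements: Sequence[SliceMeasurement],
        gaps: Sequence[float],
        selection: SliceSelection | None = None,
    ) -> "RadiusProfile":
        """Build a profile from per-slice measurements, optionally restricted
        to a contiguous slice selection (the gaps subset follows)."""
        if selection is None:
            idx = list(range(len(measurements)))
        else:
            idx = list(selection.included_indices)
        radii = tuple(measurements[i].radius for i in idx)
        areas = tuple(measurements[i].area for i in idx)
        sub_gaps = tuple(gaps[i] for i in idx[:-1])
        return cls(radii=radii, gaps=sub_gaps, areas=areas)


@dataclass(frozen=True)
class CapSpec:
    """One spherical cap: sphere radius proxy ``m`` and integration bound ``x1``."""

    m: float
    x1: float
    mode: str = "geometric"  # literal | geometric
    end: str = "superior"    # superior | inferior

    def __post_init__(self) -> None:
        if not 0.0 <= self.x1 <= self.m:
            raise ValueError(f"need 0 <= x1 <= m, got x1={self.x1}, m={self.m}")


@dataclass(frozen=True)
class VolumeEstimate:
    """A volumetry result: mid-section volume plus per-end cap volumes, mm3.

    ``total`` is exactly ``mid_volume + sum(cap_volumes)``.
    """

    method: str  # pixel_count | cylinder | cone | cone_plus_caps
    mid_volume: float
    cap_volumes: tuple[float, ...]
    total: float
    subject_id: str = ""
    eye: str = "unknown"
    cap_mode: str = "none"

    def __post_init__(self) -> None:
        if self.mid_volume < 0 or any(c < 0 for c in self.cap_volumes):
            raise ValueError("volume components must be non-negative")
        if self.total != self.mid_volume + math.fsum(self.cap_volumes):
            raise ValueError("total must equal mid_volume + sum(cap_volumes) exactly")

    @property
    def cap_volume(self) -> float:
        """Summed cap volume over both ends, mm3."""
        return math.fsum(self.cap_volumes)


# ---------------------------------------------------------------------------
# Slab primitives
# ---------------------------------------------------------------------------

def cylinder_slab(r: float, h: float) -> float:
    """Truncated-cylinder slab volume pi * r^2 * h (mm3)."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    if h <= 0:
        raise ValueError("gap must be positive")
    return math.pi * r * r * h


def frustum_slab(r_lo: float, r_hi: float, h: float) -> float:
    """Truncated-cone slab volume (pi*h/3) * (r_lo^2 + r_lo*r_hi + r_hi^2) (mm3).

    Equal radii degenerate to the cylinder; a zero radius gives a full cone.
    """
    if r_lo < 0 or r_hi < 0:
        raise ValueError("radii must be non-negative")
    if h <= 0:
        raise ValueError("gap must be positive")
    return math.pi * h / 3.0 * (r_lo * r_lo + r_lo * r_hi + r_hi * r_hi)


def cap_volume(spec: CapSpec) -> float:
    """Spherical-cap volume pi * (2 m^3/3 - m^2 x1 + x1^3/3) (mm3).

    Closed form of pi * Integral_{x1}^{m} (m^2 - x^2) dx; exactly 0 at x1 = m,
    a hemisphere at x1 = 0.
    """
    m, x1 = spec.m, spec.x1
    if x1 == m:
        return 0.0
    # max() absorbs float cancellation when x1 is within ulps of m
    return max(0.0, math.pi * (2.0 * m**3 / 3.0 - m * m * x1 + x1**3 / 3.0))


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def stack_volume(profile: RadiusProfile, method: str) -> float:
    """Accumulate N-1 slabs over the profile (mm3), ``cylinder`` or ``cone``."""
    if profile.n_slices < 2:
        raise ValueError("need at least 2 slices to stack")
    r, h = profile.radii, profile.gaps
    if method == "cylinder":
        slabs = (cylinder_slab(r[i], h[i]) for i in range(len(h)))
    elif method == "cone":
        slabs = (frustum_slab(r[i], r[i + 1], h[i]) for i in range(len(h)))
    else:
        raise ValueError(f"unknown stacking method {method!r}")
    return math.fsum(slabs)


def pixel_count_volume(profile: RadiusProfile) -> float:
    """Baseline: raw slice areas times the following gap, sum S_i * h_i (mm3)."""
    if profile.n_slices < 2:
        raise ValueError("need at least 2 slices to stack")
    return math.fsum(
        profile.areas[i] * profile.gaps[i] for i in range(len(profile.gaps))
    )


def _cap_specs(profile: RadiusProfile, cap_mode: str) -> tuple[CapSpec, CapSpec]:
    m = max(profile.radii)
    if cap_mode == "geometric":
        specs = []
        for end, r_end in (("inferior", profile.radii[0]), ("superior", profile.radii[-1])):
            if r_end >= m and len(set(profile.radii)) == 1:
                logger.warning(
                    "flat radius profile (terminal radius equals maximum); "
                    "hemisphere caps violate the sphericity assumption"
                )
            x1 = math.sqrt(max(0.0, m * m - r_end * r_end))
            specs.append(CapSpec(m=m, x1=min(x1, m), mode="geometric", end=end))
        return tuple(specs)
    if cap_mode == "literal":
        x1 = min(min(profile.radii), m)
        return (
            CapSpec(m=m, x1=x1, mode="literal", end="inferior"),
            CapSpec(m=m, x1=x1, mode="literal", end="superior"),
        )
    raise ValueError(f"unknown cap mode {cap_mode!r}")


def estimate_volume(
    profile: RadiusProfile,
    method: str = "cone",
    cap_mode: str = "geometric",
    subject_id: str = "",
    eye: str = "unknown",
) -> VolumeEstimate:
    """Full volumetry of a radius profile: mid-section stack plus end caps.

    ``cap_mode='none'`` skips the correction (required for the baseline
    methods); ``literal`` and ``geometric`` are only meaningful with the
    cone method, whose sphericity assumption the caps complete.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if cap_mode not in CAP_MODES:
        raise ValueError(f"unknown cap mode {cap_mode!r}; choose from {CAP_MODES}")
    if cap_mode != "none" and method != "cone":
        raise ValueError("cap correction is only defined for the cone method")
    if all(r == 0 for r in profile.radii):
        raise ValueError("all-zero radius profile: nothing to measure")

    if method == "pixel_count":
        mid = pixel_count_volume(profile)
    else:
        mid = stack_volume(profile, method)

    caps: tuple[float, ...] = ()
    if cap_mode != "none":
        caps = tuple(cap_volume(s) for s in _cap_specs(profile, cap_mode))

    tag = "cone_plus_caps" if caps else method
    return VolumeEstimate(
        method=tag,
        mid_volume=mid,
        cap_volumes=caps,
        total=mid + math.fsum(caps),
        subject_id=subject_id,
        eye=eye,
        cap_mode=cap_mode,
    )


def estimate_stack(
    stack: MaskStack,
    method: str = "cone",
    cap_mode: str = "geometric",
    min_radius_fraction: float = DEFAULT_MIN_RADIUS_FRACTION,
    crop_margin_px: int = 2,
) -> tuple[VolumeEstimate, list[SliceMeasurement], SliceSelection]:
    """The per-eye volumetry pipeline for one mask stack.

    Crop to the region of interest, measure every slice, apply the
    visibility selection, build the radius profile and estimate the volume.
    Returns (estimate, per-slice measurements, selection).
    """
    stack = crop_roi(stack, crop_margin_px)
    measurements = measure_slices(stack)
    selection = select_slices(measurements, min_radius_fraction)
    profile = RadiusProfile.from_measurements(measurements, stack.geometry.gaps, selection)
    estimate = estimate_volume(
        profile, method=method, cap_mode=cap_mode,
        subject_id=stack.subject_id, eye=stack.laterality,
    )
    return estimate, measurements, selection
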