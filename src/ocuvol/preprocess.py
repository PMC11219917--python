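"""HU windowing for inspection and automated slice selection.

Windowing linearly remaps the HU interval [center - width/2,
center + width/2] onto [0, 1] for display; the default soft-tissue window
(center 40 HU, width 400 HU) covers vitreous (~0-20 HU) and sclera.

Slice selection automates the manual step of keeping only slices in which
the eyeball boundary is distinctly visible: a slice is kept when its
equivalent radius reaches a configurable fraction of the stack's maximum
radius.  Near the poles of the globe the cross-section shrinks and hard
segmentations become unreliable, so terminal slices drop out; the count of
excluded terminal slices is reported so the spherical-cap correction knows
how much was removed.  Interior dropouts (a slice failing the rule between
two kept slices) are re-included to keep the selection contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mask_processing import SliceMeasurement

#: Soft-tissue display window, HU.  Overridable everywhere.
DEFAULT_WINDOW_CENTER = 40.0
DEFAULT_WINDOW_WIDTH = 400.0

#: Slices with equivalent radius below this fraction of the stack maximum
#: are treated as not distinctly visible.  At the default, sphere phantoms
#: lose roughly the outermost ~6% of axial extent per end.
DEFAULT_MIN_RADIUS_FRACTION = 0.35


@dataclass(frozen=True)
class WindowSettings:
    """Display window: ``center`` targets an HU value, ``width`` the range shown."""

    center: float = DEFAULT_WINDOW_CENTER
    width: float = DEFAULT_WINDOW_WIDTH

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")


@dataclass(frozen=True)
class SliceSelection:
    """Contiguous run of included slice ordinals plus the rule that produced it.

    ``excluded_low`` / ``excluded_high`` count terminal slices dropped below /
    above the run — the input to the end-cap correction.
    """

    included_indices: tuple[int, ...]
    rule_tag: str
    excluded_low: int = 0
    excluded_high: int = 0

    def __post_init__(self) -> None:
        idx = self.included_indices
        if idx != tuple(range(idx[0], idx[-1] + 1)):
            raise ValueError("included indices must be contiguous")


def apply_window(hu: np.ndarray, settings: WindowSettings | None = None) -> np.ndarray:
    """Linear map of [center - width/2, center + width/2] onto [0,1], clipped."""
    w = settings or WindowSettings()
    hu = np.asarray(hu, dtype=np.float64)
    lo = w.center - w.width / 2.0
    return np.clip((hu - lo) / w.width, 0.0, 1.0)


def select_slices(
    measurements: Sequence[SliceMeasurement],
    min_radius_fraction: float = DEFAULT_MIN_RADIUS_FRACTION,
) -> SliceSelection:
    """Keep slices whose radius is >= fraction * max radius; fill interior gaps.

    Raises if no slice passes (the stack has no distinctly visible slice).
    """
    if not 0.0 <= min_radius_fraction < 1.0:
        raise ValueError("min_radius_fraction must be in [0, 1)")
    radii = np.array([m.radius for m in measurements])
    if len(radii) == 0:
        raise ValueError("no measurements supplied")
    threshold = min_radius_fraction * radii.max()
    passing = np.flatnonzero(
        radii >= threshold if min_radius_fraction > 0 else radii >= 0
    )
    # fraction 0 is a vacuous threshold: keep everything, even empty slices
    if min_radius_fraction > 0:
        passing = np.flatnonzero((radii >= threshold) & (radii > 0))
    if passing.size == 0:
        raise ValueError("no slice passes the visibility threshold; nothing to measure")
    first, last = int(passing[0]), int(passing[-1])
    included = tuple(range(first, last + 1))  # interior dropouts re-included
    return SliceSelection(
        included_indices=included,
        rule_tag=f"radius_fraction>={min_radius_fraction:g}",
        excluded_low=first,
        excluded_high=len(radii) - 1 - last,
    )
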