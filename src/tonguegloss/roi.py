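"""Tongue masks and measurement-ROI placement.

The ΔL* gloss degree is read from a square region of interest that
mirrors the filter-paper moisture protocol: a 10 mm square placed on the
tongue midline with its near edge 10 mm from the tongue tip.  Tongue
masks themselves are supplied (e.g. manually annotated), matching how
the measurement region is specified in practice; this module only loads
and validates them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import EmptyMaskError, InputError, RoiOutOfBoundsError


@dataclass
class RoiSpec:
    """Geometric placement of the measurement square.

    ``tip_xy`` is the tongue-tip pixel as (row, col).  The midline
    direction points from the tip toward the tongue body;
    ``midline_angle_deg`` measures it from the +column axis, with 90°
    meaning straight down the image rows (the usual orientation of a
    protruded tongue photographed upright).  ``offset_mm`` is the
    distance from the tip to the **near edge** of the square along the
    midline (override toward offset-to-center by subtracting half the
    side if desired).
    """

    tip_xy: tuple[float, float]
    midline_angle_deg: float = 90.0
    mm_per_px: float = 0.5
    side_mm: float = 10.0
    offset_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise InputError("mm_per_px must be positive")
        if self.side_mm <= 0:
            raise InputError("side_mm must be positive")


def place_roi(spec: RoiSpec, image_shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of the measurement square for an image of ``image_shape``.

    A pixel (r, c) belongs to the square when its midline coordinate u
    (distance from the tip along the midline) satisfies
    offset ≤ u < offset + side and its transverse coordinate v satisfies
    −side/2 ≤ v < side/2, all in pixels.  The half-open intervals make
    the mask exactly side/mm_per_px pixels wide for axis-aligned
    integer geometry.

    Raises
    ------
    RoiOutOfBoundsError
        If any corner of the square lies outside the image.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    theta = math.radians(spec.midline_angle_deg)
    d = np.array([math.sin(theta), math.cos(theta)])  # (row, col) unit midline
    # Snap sub-epsilon trig residue (cos 90° = 6e-17) so axis-aligned squares
    # land on exact pixel columns/rows.
    d[np.abs(d) < 1e-12] = 0.0
    d /= np.linalg.norm(d)
    n = np.array([-d[1], d[0]])  # transverse unit
    tip = np.asarray(spec.tip_xy, dtype=float)
    side_px = spec.side_mm / spec.mm_per_px
    offset_px = spec.offset_mm / spec.mm_per_px

    corners = [
        tip + d * u + n * v
        for u in (offset_px, offset_px + side_px)
        for v in (-side_px / 2.0, side_px / 2.0)
    ]
    for corner in corners:
        if not (0 <= corner[0] <= h - 1 and 0 <= corner[1] <= w - 1):
            raise RoiOutOfBoundsError(
                f"ROI corner {tuple(np.round(corner, 1))} outside image of shape {(h, w)}"
            )

    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - tip[0]
    dc = cols - tip[1]
    u = dr * d[0] + dc * d[1]
    v = dr * n[0] + dc * n[1]
    return (
        (u >= offset_px)
        & (u < offset_px + side_px)
        & (v >= -side_px / 2.0)
        & (v < side_px / 2.0)
    )


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask PNG (nonzero → True); errors on an empty mask."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any colour/alpha channels
        arr = arr[..., :3].max(axis=-1)
    mask = arr != 0
    if not mask.any():
        raise EmptyMaskError(f"mask {path!s} contains no foreground pixels")
    return mask


#: Tongue masks and ROI masks share the same file convention.
load_tongue_mask = load_mask


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (0 = outside, 255 = inside)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))
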