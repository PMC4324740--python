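"""Gloss extraction from paired gloss/non-gloss frames.

Surface moisture shows up as specular reflection: a frame lit by diffuse
plus strong directional light carries the gloss, a frame lit by diffuse
light only does not.  Subtracting the non-gloss frame from the gloss
frame isolates the specular component; Otsu's method then splits the
difference histogram into gloss versus dark sensor noise.  Two indices
are computed from the split:

* the **glossy-area ratio** — glossy pixels as a percentage of the
  tongue-surface pixels, and
* the **gloss degree ΔL*** — the difference in mean CIELAB lightness of
  a region of interest between the two frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .colorimetry import CalibrationModel, roi_mean_lab
from .errors import DegenerateHistogramError, EmptyRoiError, InputError, ShapeMismatchError

logger = logging.getLogger(__name__)

#: Rec. 709 luminance weights used to reduce the RGB difference to one channel.
REC709_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

#: Default minimum separation of the two Otsu class means (luminance levels)
#: below which a difference image is declared gloss-free.  Specular
#: highlights add tens-to-hundreds of levels, whereas the residual noise of
#: differencing two frames spans only a few; 20 sits far above the noise and
#: far below any plausible highlight.
DEFAULT_MIN_CONTRAST = 20.0

#: Default minimum connected-component size (8-connectivity) kept in the
#: glossy mask.  Highlights are contiguous patches of liquid surface, while
#: dark-noise pixels that leak past the threshold are spatially uncorrelated
#: singletons; dropping components below a few pixels removes the latter
#: without touching any plausible highlight.
DEFAULT_MIN_BLOB_PX = 4


@dataclass
class FramePair:
    """Co-registered gloss / non-gloss frames over a common tongue mask.

    Frames are (H, W, 3) arrays on the 0–255 scale (any float or integer
    dtype); they are assumed aligned (captured ~0.1 s apart).
    """

    gloss_frame: np.ndarray
    nongloss_frame: np.ndarray
    tongue_mask: np.ndarray
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.gloss_frame = np.asarray(self.gloss_frame)
        self.nongloss_frame = np.asarray(self.nongloss_frame)
        self.tongue_mask = np.asarray(self.tongue_mask, dtype=bool)
        if self.gloss_frame.shape != self.nongloss_frame.shape:
            raise ShapeMismatchError(
                f"gloss frame shape {self.gloss_frame.shape} != non-gloss "
                f"frame shape {self.nongloss_frame.shape}"
            )
        if self.gloss_frame.ndim != 3 or self.gloss_frame.shape[-1] != 3:
            raise ShapeMismatchError(
                f"expected (H, W, 3) frames, got shape {self.gloss_frame.shape}"
            )
        if self.tongue_mask.shape != self.gloss_frame.shape[:2]:
            raise ShapeMismatchError(
                f"tongue mask shape {self.tongue_mask.shape} does not match "
                f"frames {self.gloss_frame.shape[:2]}"
            )
        if not self.tongue_mask.any():
            raise InputError("tongue mask is empty")


@dataclass
class GlossMeasurement:
    """Result of gloss extraction on one frame pair."""

    gloss_mask: np.ndarray
    otsu_threshold: float | None
    area_ratio_pct: float
    delta_L_star: float | None = None
    roi_mask: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "area_ratio_pct": round(self.area_ratio_pct, 2),
            "delta_L_star": None if self.delta_L_star is None else round(self.delta_L_star, 2),
            "otsu_threshold": self.otsu_threshold,
            "glossy_pixels": int(np.count_nonzero(self.gloss_mask)),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def subtract_pair(pair: FramePair) -> np.ndarray:
    """Clamped luminance difference, gloss minus non-gloss.

    Per-channel differences are clamped at zero (negatives are frame
    noise and slight motion, not gloss), reduced to a single channel by
    Rec. 709 luminance weighting, and zeroed outside the tongue mask.
    """
    diff = np.clip(
        pair.gloss_frame.astype(float) - pair.nongloss_frame.astype(float), 0.0, None
    )
    lum = diff @ REC709_WEIGHTS
    lum[~pair.tongue_mask] = 0.0
    return lum


def otsu_threshold(values: Sequence[float] | np.ndarray, *, n_levels: int = 256) -> float:
    """Otsu's threshold on a 256-level histogram of ``values``.

    Values are binned to integer levels 0..``n_levels``-1 (floor, then
    clipped).  The returned level t maximises the between-class variance
    w0·w1·(μ0−μ1)² of the split {levels ≤ t} | {levels > t}; ties are
    broken toward the smallest level.  Class counts and sums are
    integers, so candidate variances are compared as exact rationals —
    the argmax is free of floating-point tie ambiguity.

    Raises
    ------
    DegenerateHistogramError
        Fewer than two distinct binned levels.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateHistogramError("no values to threshold")
    levels = np.clip(np.floor(v), 0, n_levels - 1).astype(np.int64)
    counts = np.bincount(levels, minlength=n_levels)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram has fewer than two distinct levels")

    total_n = int(counts.sum())
    total_s = int((np.arange(n_levels) * counts).sum())
    best_t = None
    best_num = -1  # between-class variance as exact fraction num/den
    best_den = 1
    n0 = 0
    s0 = 0
    for t in range(n_levels - 1):
        n0 += int(counts[t])
        s0 += t * int(counts[t])
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        num = (s0 * n1 - (total_s - s0) * n0) ** 2
        den = n0 * n1
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    assert best_t is not None
    return float(best_t)


def detect_gloss(
    pair: FramePair,
    *,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
    min_blob_px: int = DEFAULT_MIN_BLOB_PX,
) -> GlossMeasurement:
    """Segment the glossy area of a frame pair and compute its area ratio.

    The glossy mask is ``difference > otsu_threshold`` intersected with
    the tongue mask, despeckled by removing connected components smaller
    than ``min_blob_px``; the ratio is expressed as a percentage of the
    tongue-mask area.  Two degenerate situations yield an empty mask and
    a ratio of 0 (logged): a constant difference image, and a split
    whose class means are separated by less than ``min_contrast``
    luminance levels — the signature of a gloss-free pair, where Otsu
    would otherwise bisect pure sensor noise.
    """
    from scipy import ndimage

    diff = subtract_pair(pair)
    tongue = pair.tongue_mask
    empty = np.zeros_like(tongue, dtype=bool)
    try:
        threshold = otsu_threshold(diff[tongue])
    except DegenerateHistogramError:
        logger.info("constant difference image: no gloss detected")
        return GlossMeasurement(empty, None, 0.0)
    gloss_mask = (diff > threshold) & tongue
    if min_blob_px > 1 and gloss_mask.any():
        labels, n_comp = ndimage.label(gloss_mask, structure=np.ones((3, 3), bool))
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_blob_px
        keep[0] = False
        gloss_mask = keep[labels]
    if not gloss_mask.any():
        return GlossMeasurement(empty, threshold, 0.0)
    in_tongue = diff[tongue]
    mu1 = in_tongue[in_tongue > threshold].mean()
    low = in_tongue[in_tongue <= threshold]
    mu0 = low.mean() if low.size else 0.0
    if mu1 - mu0 < min_contrast:
        logger.info(
            "between-class contrast %.2f below %.2f: treating pair as gloss-free",
            mu1 - mu0, min_contrast,
        )
        return GlossMeasurement(empty, threshold, 0.0)
    area_ratio = 100.0 * np.count_nonzero(gloss_mask) / np.count_nonzero(tongue)
    logger.debug("Otsu threshold %.1f, glossy-area ratio %.2f%%", threshold, area_ratio)
    return GlossMeasurement(gloss_mask, threshold, float(area_ratio))


def gloss_degree(
    pair: FramePair, roi_mask: np.ndarray, model: CalibrationModel
) -> float:
    """ΔL* gloss degree: ROI mean lightness, gloss frame minus non-gloss frame.

    The mean RGB of the ROI is computed first and converted to L*a*b*
    second, in each frame; the result is the L* difference.  It is not
    clamped — a dry tongue can yield values near (or marginally below)
    zero.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise EmptyRoiError("ROI mask selects no pixels")
    lab_gloss = roi_mean_lab(pair.gloss_frame, roi_mask, model)
    lab_nongloss = roi_mean_lab(pair.nongloss_frame, roi_mask, model)
    return lab_gloss.L_star - lab_nongloss.L_star


def measure_pair(
    pair: FramePair,
    roi_mask: np.ndarray | None = None,
    model: CalibrationModel | None = None,
    *,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
) -> GlossMeasurement:
    """Full gloss measurement: area ratio always, ΔL* when an ROI is given."""
    measurement = detect_gloss(pair, min_contrast=min_contrast)
    if roi_mask is not None:
        if model is None:
            model = CalibrationModel.identity()
        measurement.delta_L_star = gloss_degree(pair, roi_mask, model)
        measurement.roi_mask = np.asarray(roi_mask, dtype=bool)
    return measurement
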