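"""Camera colorimetry: chart-based RGB→XYZ calibration and CIELAB conversion.

The camera is characterised from a colour chart photographed in the same
illumination used for tongue imaging: the reference tristimulus values
(XYZ) of each patch are regressed on the measured mean sensor RGB of that
patch, giving an affine RGB→XYZ transform (one multiple regression per
XYZ channel).  Pixel values and ROI means are then expressed in CIE1976
L*a*b*, whose lightness L* is the axis the brightness-based gloss index
is defined on.

All arithmetic is floating point on the native 8-bit (0–255) sensor
scale, so the reference white also lives on that scale: its Y maps to
L* = 100.  By default the white point is the reference XYZ of the
chart's white patch; a standard illuminant may be supplied instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationDegenerateError,
    EmptyRoiError,
    InputError,
    InsufficientPatchesError,
    ShapeMismatchError,
)

logger = logging.getLogger(__name__)

# CIE1976 companding constants: threshold (6/29)^3 and linear-branch slope.
_CIE_EPS = 216.0 / 24389.0
_CIE_KAPPA = 24389.0 / 27.0

_CHART_COLUMNS = ["patch_id", "X", "Y", "Z", "R", "G", "B"]


@dataclass(frozen=True)
class LabColor:
    """A CIE1976 L*a*b* triple (L* in [0, 100] for in-gamut stimuli)."""

    L_star: float
    a_star: float
    b_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star])


@dataclass(frozen=True)
class ChartPatch:
    patch_id: str
    xyz: tuple[float, float, float]
    rgb: tuple[float, float, float]


@dataclass
class ChartReference:
    """Colour-chart patch table: reference XYZ and measured mean RGB per patch."""

    patches: list[ChartPatch]

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) reference tristimulus values."""
        return np.array([p.xyz for p in self.patches], dtype=float)

    @property
    def rgb(self) -> np.ndarray:
        """(n, 3) measured mean sensor RGB values."""
        return np.array([p.rgb for p in self.patches], dtype=float)

    def white_patch(self) -> ChartPatch:
        """The patch named ``white`` (case-insensitive), else the one of maximal Y."""
        for p in self.patches:
            if p.patch_id.strip().lower() == "white":
                return p
        return max(self.patches, key=lambda p: p.xyz[1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChartReference":
        df = pd.read_csv(path)
        for col in _CHART_COLUMNS:
            if col not in df.columns:
                raise InputError(f"chart CSV {path!s} is missing required column {col!r}")
        patches = [
            ChartPatch(str(row.patch_id), (row.X, row.Y, row.Z), (row.R, row.G, row.B))
            for row in df.itertuples()
        ]
        return cls(patches)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"patch_id": p.patch_id, "X": p.xyz[0], "Y": p.xyz[1], "Z": p.xyz[2],
             "R": p.rgb[0], "G": p.rgb[1], "B": p.rgb[2]}
            for p in self.patches
        ]
        pd.DataFrame(rows, columns=_CHART_COLUMNS).to_csv(path, index=False)


@dataclass
class CalibrationModel:
    """Fitted RGB→XYZ transform plus the reference white for L*a*b*.

    ``matrix`` has one row per XYZ channel and one column per regression
    term; for the default affine fit the terms are (R, G, B, 1), i.e. a
    3×4 matrix.  With ``quadratic=True`` the design is extended by the
    six second-order monomials (R², G², B², RG, RB, GB) before the
    constant term.
    """

    matrix: np.ndarray
    white_point: np.ndarray
    residual_rms: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quadratic: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.white_point = np.asarray(self.white_point, dtype=float)
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        if self.matrix.shape != (3, 10 if self.quadratic else 4):
            raise InputError(
                f"calibration matrix has shape {self.matrix.shape}, expected "
                f"{(3, 10 if self.quadratic else 4)}"
            )
        if np.any(self.white_point <= 0):
            raise InputError("white point components must be positive")

    @classmethod
    def identity(cls, white_point: Sequence[float] = (255.0, 255.0, 255.0)) -> "CalibrationModel":
        """RGB treated as XYZ directly (useful default for uncalibrated sensors)."""
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]), np.asarray(white_point, float))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "matrix": self.matrix.tolist(),
            "white_point": self.white_point.tolist(),
            "residual_rms": self.residual_rms.tolist(),
            "quadratic": self.quadratic,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        try:
            return cls(
                np.asarray(payload["matrix"], float),
                np.asarray(payload["white_point"], float),
                np.asarray(payload.get("residual_rms", np.zeros(3)), float),
                bool(payload.get("quadratic", False)),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(f"calibration JSON {path!s} is missing key {exc}") from exc


def _design_matrix(rgb: np.ndarray, quadratic: bool) -> np.ndarray:
    """Regression terms for each RGB vector; last column is the constant 1."""
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cols = [r, g, b]
    if quadratic:
        cols += [r * r, g * g, b * b, r * g, r * b, g * b]
    cols.append(np.ones_like(r))
    return np.stack(cols, axis=-1)


def fit_calibration(
    chart: ChartReference,
    *,
    white_point: Sequence[float] | None = None,
    quadratic: bool = False,
) -> CalibrationModel:
    """Least-squares fit of the RGB→XYZ transform to a chart.

    One ordinary-least-squares multiple regression per XYZ channel, of
    the reference tristimulus value on the measured patch RGB (affine
    terms by default).  The white point defaults to the reference XYZ of
    the chart's white patch.

    Raises
    ------
    InsufficientPatchesError
        Fewer patches than regression terms.
    CalibrationDegenerateError
        Patch RGBs do not span the design space (rank-deficient fit).
    """
    n_terms = 10 if quadratic else 4
    if chart.n_patches < n_terms:
        raise InsufficientPatchesError(
            f"need at least {n_terms} patches for this fit, got {chart.n_patches}"
        )
    design = _design_matrix(chart.rgb, quadratic)
    if np.linalg.matrix_rank(design) < n_terms:
        raise CalibrationDegenerateError(
            "chart patch RGBs are degenerate: regression design matrix is rank-deficient"
        )
    coef, *_ = np.linalg.lstsq(design, chart.xyz, rcond=None)
    matrix = coef.T  # rows -> X, Y, Z
    residuals = design @ coef - chart.xyz
    residual_rms = np.sqrt(np.mean(residuals**2, axis=0))
    if white_point is None:
        white = np.asarray(chart.white_patch().xyz, dtype=float)
    else:
        white = np.asarray(white_point, dtype=float)
    model = CalibrationModel(matrix, white, residual_rms, quadratic)
    logger.info("calibration fitted: residual RMS (X, Y, Z) = %s", residual_rms)
    return model


def rgb_to_xyz(rgb: Sequence[float] | np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Apply the fitted transform to a triple or an (..., 3) pixel array."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ShapeMismatchError(f"expected trailing axis of size 3, got shape {rgb.shape}")
    return _design_matrix(rgb, model.quadratic) @ model.matrix.T


def xyz_to_lab(
    xyz: Sequence[float] | np.ndarray, white_point: Sequence[float]
) -> LabColor | np.ndarray:
    """CIE1976 L*a*b* from tristimulus values and a reference white.

    Uses the standard two-branch companding function (cube root above
    (6/29)³, linear below).  Negative tristimulus components — possible
    when a noisy sensor value is extrapolated through the calibration —
    are clamped to zero with a logged warning.

    Returns a :class:`LabColor` for a single triple, else an (..., 3)
    array of (L*, a*, b*).
    """
    white = np.asarray(white_point, dtype=float)
    if np.any(white <= 0):
        raise InputError("white point components must be positive")
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ShapeMismatchError(f"expected trailing axis of size 3, got shape {xyz.shape}")
    if np.any(xyz < 0):
        logger.warning("negative tristimulus component(s) clamped to 0")
        xyz = np.clip(xyz, 0.0, None)
    t = xyz / white
    f = np.where(t > _CIE_EPS, np.cbrt(t), (_CIE_KAPPA * t + 16.0) / 116.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    if xyz.ndim == 1:
        return LabColor(float(L), float(a), float(b))
    return np.stack([L, a, b], axis=-1)


def roi_mean_lab(
    image: np.ndarray, roi_mask: np.ndarray, model: CalibrationModel
) -> LabColor:
    """L*a*b* of the ROI's mean colour (RGB is averaged first, then converted)."""
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ShapeMismatchError(f"expected an (H, W, 3) image, got shape {image.shape}")
    if roi_mask.shape != image.shape[:2]:
        raise ShapeMismatchError(
            f"ROI mask shape {roi_mask.shape} does not match image {image.shape[:2]}"
        )
    if not roi_mask.any():
        raise EmptyRoiError("ROI mask selects no pixels")
    mean_rgb = image[roi_mask].mean(axis=0)
    lab = xyz_to_lab(rgb_to_xyz(mean_rgb, model), model.white_point)
    assert isinstance(lab, LabColor)
    return lab
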