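"""Synthetic imagery and datasets with ground truth.

No photographs or weighings are deposited with the measurement protocol
this package implements, so every pipeline input is emulated here with
known ground truth:

* colour charts rendered through a known camera matrix (inverse
  problem: patch RGBs are chosen so the matrix maps them onto canonical
  reference XYZs), optionally noised;
* gloss/non-gloss tongue pairs — an elliptical diffuse tongue plus an
  additive specular speckle blob of an exact pixel count — with the
  tongue and speckle masks returned alongside;
* drying series in which the speckle area decays exponentially over the
  protrusion, and between-series moisture recovery following
  1 − exp(−t/τ);
* (gloss degree, moisture) records drawn from a known regression line
  with Gaussian noise.

Every generator is a pure function of its seed, and downstream tests
read ground truth from the returned values, never from the images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .colorimetry import ChartPatch, ChartReference
from .errors import InputError
from .gloss import FramePair
from .moisture import GlossMoistureRecord
from .series import FrameSeries, RecoveryResult

# Canonical 24-patch chart: the familiar colour-rendition target, as
# (name, sRGB).  Reference XYZs are derived once below by linearising
# these coordinates and applying the standard sRGB→XYZ (D65) matrix,
# kept on the 0–255 working scale.
_CHART_SRGB: list[tuple[str, tuple[int, int, int]]] = [
    ("dark skin", (115, 82, 68)),
    ("light skin", (194, 150, 130)),
    ("blue sky", (98, 122, 157)),
    ("foliage", (87, 108, 67)),
    ("blue flower", (133, 128, 177)),
    ("bluish green", (103, 189, 170)),
    ("orange", (214, 126, 44)),
    ("purplish blue", (80, 91, 166)),
    ("moderate red", (193, 90, 99)),
    ("purple", (94, 60, 108)),
    ("yellow green", (157, 188, 64)),
    ("orange yellow", (224, 163, 46)),
    ("blue", (56, 61, 150)),
    ("green", (70, 148, 73)),
    ("red", (175, 54, 60)),
    ("yellow", (231, 199, 31)),
    ("magenta", (187, 86, 149)),
    ("cyan", (8, 133, 161)),
    ("white", (243, 243, 242)),
    ("neutral 8", (200, 200, 200)),
    ("neutral 6.5", (160, 160, 160)),
    ("neutral 5", (122, 122, 121)),
    ("neutral 3.5", (85, 85, 85)),
    ("black", (52, 52, 52)),
]

_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: A plausible (non-identity, well-conditioned) camera RGB→XYZ matrix used
#: as the default ground truth when simulating charts from the CLI.
DEFAULT_CAMERA_MATRIX = np.array(
    [
        [0.90, 0.18, 0.05, 2.0],
        [0.25, 0.70, 0.08, 1.0],
        [0.03, 0.12, 0.92, 3.0],
    ]
)


def _linearize_srgb(c: np.ndarray) -> np.ndarray:
    c = c / 255.0
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def chart_reference_xyz() -> tuple[list[str], np.ndarray]:
    """Canonical patch names and reference XYZs on the 0–255 scale."""
    names = [name for name, _ in _CHART_SRGB]
    srgb = np.array([rgb for _, rgb in _CHART_SRGB], dtype=float)
    xyz = _linearize_srgb(srgb) @ _SRGB_TO_XYZ.T * 255.0
    return names, xyz


def make_chart(
    matrix: np.ndarray, noise_sigma: float = 0.0, seed: int | None = None
) -> ChartReference:
    """Render the canonical chart through a known camera matrix.

    Solves the inverse problem: for each reference XYZ, the measured RGB
    is the vector the affine ``matrix`` (3×4, columns R, G, B, 1) maps
    onto that XYZ, plus optional i.i.d. Gaussian sensor noise of
    ``noise_sigma`` (8-bit scale).  RGBs are not clipped, so a noiseless
    chart round-trips through calibration exactly; for physically
    plausible matrices they stay within the nominal sensor range.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 4):
        raise InputError(f"camera matrix must be 3x4, got {matrix.shape}")
    linear, offset = matrix[:, :3], matrix[:, 3]
    if abs(np.linalg.det(linear)) < 1e-12:
        raise InputError("camera matrix has a non-invertible linear part")
    names, xyz = chart_reference_xyz()
    rgb = np.linalg.solve(linear, (xyz - offset).T).T
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sigma, rgb.shape)
    return ChartReference(
        [ChartPatch(name, tuple(x), tuple(c)) for name, x, c in zip(names, xyz, rgb)]
    )


@dataclass
class TongueSceneParams:
    """Parameters of one synthetic gloss/non-gloss acquisition.

    Defaults give a ~13 000-pixel elliptical tongue on a dark
    background, a reddish diffuse base colour, a specular speckle of
    +120 luminance levels and per-pixel sensor noise of σ = 2 levels —
    a gloss-to-noise contrast in line with a strongly directional light
    source against the residual noise of frame differencing.
    """

    image_size: tuple[int, int] = (200, 260)
    tongue_center: tuple[float, float] = (100.0, 130.0)
    tongue_axes: tuple[float, float] = (55.0, 75.0)
    base_color_rgb: tuple[float, float, float] = (150.0, 80.0, 80.0)
    background_rgb: tuple[float, float, float] = (20.0, 18.0, 18.0)
    speckle_px: int = 500
    speckle_amplitude: float = 120.0
    noise_sigma: float = 2.0
    n_speckle_seeds: int = 3
    seed: int = 0


@dataclass
class DryingParams:
    """Exponential drying of the speckle area during protrusion.

    ``decay_time_s`` of 20 s halves the glossy area in ~14 s, between
    the fast- and slow-drying behaviours seen across subjects.
    ``recovery_tau_s`` is the time constant of between-series moisture
    recovery, 1 − exp(−t/τ).
    """

    initial_speckle_px: int = 500
    decay_time_s: float = 20.0
    frame_times_s: Sequence[float] = field(default_factory=lambda: tuple(range(21)))
    recovery_tau_s: float = 60.0

    def __post_init__(self) -> None:
        if self.decay_time_s <= 0 or self.recovery_tau_s <= 0:
            raise InputError("time constants must be positive")
        times = list(self.frame_times_s)
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise InputError("frame_times_s must be strictly increasing")


def tongue_mask_from_params(params: TongueSceneParams) -> np.ndarray:
    h, w = params.image_size
    rows, cols = np.mgrid[0:h, 0:w]
    cr, cc = params.tongue_center
    ar, ac = params.tongue_axes
    return ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0


def _speckle_order(
    tongue: np.ndarray, n_px: int, n_seeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Flat pixel indices of a contiguous blob, in growth order.

    Blobs grow from random seed pixels by 8-connected dilation inside
    the tongue mask; within each dilation ring, pixels are ordered by
    raster index so that truncation to an exact count is deterministic.
    """
    available = np.flatnonzero(tongue)
    if n_px > available.size:
        raise InputError(f"speckle_px={n_px} exceeds tongue area {available.size}")
    seeds = rng.choice(available, size=min(n_seeds, available.size), replace=False)
    blob = np.zeros(tongue.shape, dtype=bool)
    blob.ravel()[seeds] = True
    order = list(np.sort(seeds))
    structure = np.ones((3, 3), dtype=bool)
    while len(order) < n_px:
        ring = ndimage.binary_dilation(blob, structure=structure) & tongue & ~blob
        new = np.flatnonzero(ring)
        if new.size == 0:  # blob filled its basin; restart from a fresh seed
            remaining = np.setdiff1d(available, np.flatnonzero(blob), assume_unique=False)
            new = rng.choice(remaining, size=1)
        order.extend(new.tolist())
        blob.ravel()[new] = True
    return np.asarray(order[:n_px], dtype=np.int64)


def _render_pair(
    params: TongueSceneParams,
    tongue: np.ndarray,
    speckle_flat: np.ndarray,
    rng: np.random.Generator,
    timestamp_s: float = 0.0,
) -> tuple[FramePair, np.ndarray]:
    h, w = params.image_size
    base = np.empty((h, w, 3), dtype=float)
    base[...] = params.background_rgb
    base[tongue] = params.base_color_rgb

    speckle = np.zeros((h, w), dtype=bool)
    speckle.ravel()[speckle_flat] = True

    nongloss = base + rng.normal(0.0, params.noise_sigma, base.shape)
    gloss = base.copy()
    gloss[speckle] += params.speckle_amplitude
    gloss += rng.normal(0.0, params.noise_sigma, base.shape)

    to_u8 = lambda a: np.clip(np.rint(a), 0, 255).astype(np.uint8)
    pair = FramePair(to_u8(gloss), to_u8(nongloss), tongue, timestamp_s=timestamp_s)
    return pair, speckle


def make_pair(params: TongueSceneParams) -> tuple[FramePair, np.ndarray]:
    """One gloss/non-gloss pair plus the ground-truth speckle mask.

    The non-gloss frame is the diffuse tongue plus sensor noise; the
    gloss frame is the same underlying scene with ``speckle_amplitude``
    added on a contiguous blob of exactly ``speckle_px`` pixels and an
    independent noise draw.
    """
    rng = np.random.default_rng(params.seed)
    tongue = tongue_mask_from_params(params)
    if params.speckle_px > 0:
        flat = _speckle_order(tongue, params.speckle_px, params.n_speckle_seeds, rng)
    else:
        flat = np.empty(0, dtype=np.int64)
    return _render_pair(params, tongue, flat, rng)


def make_series(
    scene: TongueSceneParams, drying: DryingParams
) -> tuple[FrameSeries, list[float]]:
    """A drying protrusion series plus ground-truth glossy fractions (%).

    The speckle pixel count at time t is
    round(initial · exp(−t/decay_time_s)); the blob shrinks through the
    same growth ordering at every time, so masks are nested and the
    ground-truth fraction is monotone non-increasing.
    """
    rng = np.random.default_rng(scene.seed)
    tongue = tongue_mask_from_params(scene)
    area = int(np.count_nonzero(tongue))
    order = (
        _speckle_order(tongue, drying.initial_speckle_px, scene.n_speckle_seeds, rng)
        if drying.initial_speckle_px > 0
        else np.empty(0, dtype=np.int64)
    )
    pairs, fractions = [], []
    for t in drying.frame_times_s:
        decay = 1.0 if math.isinf(drying.decay_time_s) else math.exp(-t / drying.decay_time_s)
        k = int(round(drying.initial_speckle_px * decay))
        pair, _ = _render_pair(scene, tongue, order[:k], rng, timestamp_s=float(t))
        pairs.append(pair)
        fractions.append(100.0 * k / area)
    return FrameSeries(pairs), fractions


def recovery_fraction(interval_s: float, tau_s: float) -> float:
    """Modelled fraction of gloss recovered after a rest of ``interval_s``."""
    return 1.0 - math.exp(-interval_s / tau_s)


def make_recovery_series(
    scene: TongueSceneParams, drying: DryingParams, interval_s: float
) -> tuple[FrameSeries, FrameSeries]:
    """Two drying series separated by a rest interval.

    The second series starts from initial · (1 − exp(−interval/τ))
    speckle pixels — partially recovered moisture — and dries with the
    same time constant.
    """
    first, _ = make_series(scene, drying)
    frac = recovery_fraction(interval_s, drying.recovery_tau_s)
    second_drying = DryingParams(
        initial_speckle_px=int(round(drying.initial_speckle_px * frac)),
        decay_time_s=drying.decay_time_s,
        frame_times_s=drying.frame_times_s,
        recovery_tau_s=drying.recovery_tau_s,
    )
    second_scene = TongueSceneParams(**{**scene.__dict__, "seed": scene.seed + 1})
    second, _ = make_series(second_scene, second_drying)
    return first, second


def simulate_recovery_curve(
    intervals_s: Sequence[float], tau_s: float = 60.0, base_ratio_pct: float = 5.0
) -> list[RecoveryResult]:
    """Closed-form recovery results under the exponential recovery model."""
    return [
        RecoveryResult(
            first_series_stat=base_ratio_pct,
            second_series_stat=base_ratio_pct * recovery_fraction(t, tau_s),
            interval_s=float(t),
        )
        for t in intervals_s
    ]


def make_moisture_dataset(
    slope: float = 4.2e-4,
    intercept: float = -0.017,
    n: int = 25,
    g_range: tuple[float, float] = (41.0, 100.0),
    noise_sigma: float = 0.005,
    seed: int | None = None,
    *,
    floor_at_zero: bool = True,
) -> list[GlossMoistureRecord]:
    """(gloss degree, moisture) records from a known regression line.

    Gloss degrees are uniform on ``g_range``; moisture is
    slope·g + intercept + N(0, noise_sigma), floored at 0 by default
    (a filter paper cannot lose weight).  The lower half of the gloss
    range is labelled ``dry`` and the upper half ``normal`` (13 dry /
    12 normal at the default n = 25).  Note that with noise comparable
    to the line values, flooring censors low-gloss records and biases
    OLS recovery of the generative parameters; pass
    ``floor_at_zero=False`` for unbiased parameter-recovery studies.
    """
    if n < 3:
        raise InputError(f"need n >= 3 records, got {n}")
    rng = np.random.default_rng(seed)
    g = rng.uniform(g_range[0], g_range[1], n)
    m = slope * g + intercept + rng.normal(0.0, noise_sigma, n)
    if floor_at_zero:
        m = np.maximum(m, 0.0)
    n_dry = math.ceil(n / 2)
    dry_idx = set(np.argsort(g)[:n_dry].tolist())
    return [
        GlossMoistureRecord(
            subject_id=f"s{i + 1:02d}",
            state="dry" if i in dry_idx else "normal",
            gloss_degree=float(g[i]),
            moisture_mg=float(m[i]),
        )
        for i in range(n)
    ]
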