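"""Serial gloss analysis: drying trajectories and moisture recovery.

A protruded tongue dries, so its glossy-area ratio falls over the ~20 s
an acquisition lasts.  Repeating the acquisition after a rest interval
tests whether surface moisture has recovered; the recovery fraction
(second-series statistic ÷ first-series statistic) as a function of the
interval locates the shortest rest after which measurements are
repeatable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gloss import DEFAULT_MIN_CONTRAST, FramePair, detect_gloss
from .errors import DegenerateDataError, InputError

logger = logging.getLogger(__name__)

_MANIFEST_COLUMNS = ["time_s", "gloss_frame_path", "nongloss_frame_path"]

#: Smallest recovery fraction counted as full recovery by default.
DEFAULT_RECOVERY_CRITERION = 0.95


@dataclass
class FrameSeries:
    """Time-ordered frame pairs from one protrusion episode.

    ``protrusion_start_s`` anchors trajectory time 0; it defaults to the
    first pair's timestamp.
    """

    pairs: list[FramePair]
    protrusion_start_s: float | None = None

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InputError("series contains no frame pairs")
        times = [p.timestamp_s for p in self.pairs]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise InputError("frame-pair timestamps must be strictly increasing")
        if self.protrusion_start_s is None:
            self.protrusion_start_s = times[0]


@dataclass
class RecoveryResult:
    """Gloss statistics of two protrusion series separated by a rest interval."""

    first_series_stat: float
    second_series_stat: float
    interval_s: float
    recovery_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise InputError("interval_s must be positive")
        if self.recovery_fraction is None:
            if self.first_series_stat == 0:
                raise DegenerateDataError(
                    "first-series gloss statistic is zero: recovery fraction undefined"
                )
            self.recovery_fraction = self.second_series_stat / self.first_series_stat


def gloss_trajectory(
    series: FrameSeries, *, min_contrast: float = DEFAULT_MIN_CONTRAST
) -> pd.DataFrame:
    """Glossy-area ratio per frame pair, timed from protrusion start.

    Returns a DataFrame with columns ``time_s``, ``area_ratio_pct`` and
    ``otsu_threshold`` (NaN where the pair was degenerate).
    """
    rows = []
    for pair in series.pairs:
        m = detect_gloss(pair, min_contrast=min_contrast)
        rows.append(
            {
                "time_s": pair.timestamp_s - series.protrusion_start_s,
                "area_ratio_pct": m.area_ratio_pct,
                "otsu_threshold": np.nan if m.otsu_threshold is None else m.otsu_threshold,
            }
        )
    return pd.DataFrame(rows)


def _series_stat(series: FrameSeries, summary: str, min_contrast: float) -> float:
    ratios = gloss_trajectory(series, min_contrast=min_contrast)["area_ratio_pct"]
    if summary == "initial":
        return float(ratios.iloc[0])
    if summary == "mean":
        return float(ratios.mean())
    raise InputError(f"summary must be 'initial' or 'mean', got {summary!r}")


def compare_series(
    first: FrameSeries,
    second: FrameSeries,
    interval_s: float,
    *,
    summary: str = "initial",
    min_contrast: float = DEFAULT_MIN_CONTRAST,
) -> RecoveryResult:
    """Recovery fraction of a repeated acquisition after a rest interval.

    Each series is summarised by its initial glossy-area ratio by
    default (the value immediately after the tongue is stuck out), or by
    its mean over the series with ``summary="mean"``.
    """
    first_stat = _series_stat(first, summary, min_contrast)
    second_stat = _series_stat(second, summary, min_contrast)
    return RecoveryResult(first_stat, second_stat, interval_s)


def recovery_curve(
    results: Sequence[RecoveryResult],
    *,
    criterion: float = DEFAULT_RECOVERY_CRITERION,
) -> tuple[pd.DataFrame, float | None]:
    """Tabulate recovery fraction against rest interval.

    Returns the table sorted by interval (columns ``interval_s``,
    ``first_series_stat``, ``second_series_stat``, ``recovery_fraction``,
    ``full_recovery``) and the smallest interval whose fraction meets
    ``criterion`` (None if no interval does).
    """
    if not results:
        raise InputError("no recovery results given")
    df = pd.DataFrame(
        {
            "interval_s": [r.interval_s for r in results],
            "first_series_stat": [r.first_series_stat for r in results],
            "second_series_stat": [r.second_series_stat for r in results],
            "recovery_fraction": [r.recovery_fraction for r in results],
        }
    ).sort_values("interval_s", ignore_index=True)
    df["full_recovery"] = df["recovery_fraction"] >= criterion
    recovered = df.loc[df["full_recovery"], "interval_s"]
    min_interval = float(recovered.iloc[0]) if not recovered.empty else None
    if min_interval is None:
        logger.info("no tested interval reaches recovery criterion %.2f", criterion)
    else:
        logger.info("full recovery (≥%.2f) first reached at %.0f s", criterion, min_interval)
    return df, min_interval


def load_series_manifest(
    path: str | Path, tongue_mask: np.ndarray, *, protrusion_start_s: float | None = None
) -> FrameSeries:
    """Build a :class:`FrameSeries` from a manifest CSV of frame paths.

    The manifest needs columns ``time_s``, ``gloss_frame_path`` and
    ``nongloss_frame_path``; relative paths resolve against the manifest's
    directory.
    """
    import imageio.v3 as iio

    path = Path(path)
    df = pd.read_csv(path)
    for col in _MANIFEST_COLUMNS:
        if col not in df.columns:
            raise InputError(f"series manifest {path!s} is missing required column {col!r}")
    if df.empty:
        raise InputError(f"series manifest {path!s} lists no frames")

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else path.parent / p

    pairs = []
    for row in df.sort_values("time_s").itertuples():
        pairs.append(
            FramePair(
                iio.imread(_resolve(row.gloss_frame_path)),
                iio.imread(_resolve(row.nongloss_frame_path)),
                tongue_mask,
                timestamp_s=float(row.time_s),
            )
        )
    return FrameSeries(pairs, protrusion_start_s=protrusion_start_s)
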