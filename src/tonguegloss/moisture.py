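"""Gloss-to-moisture regression.

Tongue-surface moisture (the water gain of a 10 mm filter paper, in mg)
is linearly related to the gloss degree measured in the image:

    moisture_mg = slope · gloss_degree + intercept

The published coefficients (slope 4.2×10⁻⁴ mg per gloss-degree unit,
intercept −0.017 mg, Pearson r = 0.80 over 25 subjects) ship as the
bundled default model.  New models can be fitted from (gloss, moisture)
records by ordinary least squares.

Which gloss index feeds the model — the ΔL* brightness difference or
the glossy-area percentage — is carried as model metadata (default
ΔL*); the regression itself is index-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InputError

_RECORD_COLUMNS = ["subject_id", "state", "gloss_degree", "moisture_mg"]
_STATES = ("normal", "dry")


@dataclass(frozen=True)
class GlossMoistureRecord:
    """One subject's paired gloss index and filter-paper moisture (mg).

    ``moisture_mg`` is physically non-negative for real weighings; it is
    not hard-validated so that simulation studies may carry unclipped
    values.
    """

    subject_id: str
    state: str
    gloss_degree: float
    moisture_mg: float

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise InputError(f"state must be one of {_STATES}, got {self.state!r}")


@dataclass
class MoistureModel:
    """Linear gloss→moisture map with fit diagnostics."""

    slope: float
    intercept: float
    r: float | None = None
    n: int | None = None
    p_value: float | None = None
    index: str = "delta_L"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "n": self.n,
            "p_value": self.p_value,
            "index": self.index,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MoistureModel":
        payload = json.loads(Path(path).read_text())
        for key in ("slope", "intercept"):
            if key not in payload:
                raise InputError(f"moisture model JSON {path!s} is missing key {key!r}")
        return cls(
            float(payload["slope"]),
            float(payload["intercept"]),
            payload.get("r"),
            payload.get("n"),
            payload.get("p_value"),
            payload.get("index", "delta_L"),
        )


def default_model() -> MoistureModel:
    """The bundled published regression (slope 4.2×10⁻⁴, intercept −0.017)."""
    path = resources.files("tonguegloss").joinpath("data/default_moisture_model.json")
    payload = json.loads(path.read_text())
    return MoistureModel(
        float(payload["slope"]), float(payload["intercept"]),
        payload.get("r"), payload.get("n"), index=payload.get("index", "delta_L"),
    )


@dataclass(frozen=True)
class MoistureEstimate:
    """Predicted moisture with the raw (unclamped) regression value retained."""

    moisture_mg: float
    raw_mg: float
    clamped: bool


def estimate_moisture(gloss_degree: float, model: MoistureModel | None = None) -> MoistureEstimate:
    """Predict moisture (mg) from a gloss-degree value.

    Negative predictions — possible below the regression line's root —
    are reported as 0 with ``clamped`` set, the raw value preserved.
    """
    if model is None:
        model = default_model()
    raw = model.slope * float(gloss_degree) + model.intercept
    if raw < 0:
        return MoistureEstimate(0.0, raw, True)
    return MoistureEstimate(raw, raw, False)


def _arrays(records: Iterable[GlossMoistureRecord]) -> tuple[np.ndarray, np.ndarray]:
    records = list(records)
    g = np.array([rec.gloss_degree for rec in records], dtype=float)
    m = np.array([rec.moisture_mg for rec in records], dtype=float)
    return g, m


def fit_regression(
    records: Sequence[GlossMoistureRecord],
    *,
    state: str | None = None,
    index: str = "delta_L",
) -> MoistureModel:
    """OLS fit of moisture on gloss degree over the given records.

    Normal and dry-state subjects are pooled by default; pass ``state``
    to fit one stratum only.

    Raises
    ------
    DegenerateDataError
        Fewer than 3 records, or all gloss degrees equal.
    """
    if state is not None:
        records = [rec for rec in records if rec.state == state]
    g, m = _arrays(records)
    if g.size < 3:
        raise DegenerateDataError(f"need at least 3 records to fit, got {g.size}")
    if np.ptp(g) == 0:
        raise DegenerateDataError("all gloss degrees are equal: regression is degenerate")
    res = stats.linregress(g, m)
    return MoistureModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=int(g.size),
        p_value=float(res.pvalue),
        index=index,
    )


def pearson_r(records: Sequence[GlossMoistureRecord]) -> tuple[float, float]:
    """Pearson product-moment correlation of moisture and gloss degree.

    Returns ``(r, p)`` where p is the two-sided significance of
    H0: ρ = 0 under the usual t-distribution test.
    """
    g, m = _arrays(records)
    if g.size < 3:
        raise DegenerateDataError(f"need at least 3 records, got {g.size}")
    if np.ptp(g) == 0 or np.ptp(m) == 0:
        raise DegenerateDataError("zero variance in gloss degree or moisture")
    res = stats.pearsonr(g, m)
    return float(res.statistic), float(res.pvalue)


def records_to_csv(records: Sequence[GlossMoistureRecord], path: str | Path) -> None:
    rows = [
        {"subject_id": rec.subject_id, "state": rec.state,
         "gloss_degree": rec.gloss_degree, "moisture_mg": rec.moisture_mg}
        for rec in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[GlossMoistureRecord]:
    df = pd.read_csv(path)
    for col in _RECORD_COLUMNS:
        if col not in df.columns:
            raise InputError(f"records CSV {path!s} is missing required column {col!r}")
    return [
        GlossMoistureRecord(str(row.subject_id), str(row.state),
                            float(row.gloss_degree), float(row.moisture_mg))
        for row in df.itertuples()
    ]
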