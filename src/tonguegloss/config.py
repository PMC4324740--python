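"""YAML run configuration shared by the CLI commands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InputError

_GLOSS_INDICES = ("delta_L", "area_pct")


@dataclass
class RunConfig:
    """Defaults a YAML config file may supply to any CLI command.

    Command-line flags always win over config values.  ``roi`` holds the
    geometric ROI placement (keys ``tip_row``, ``tip_col``,
    ``midline_angle_deg``, ``side_mm``, ``offset_mm``) used when no ROI
    mask is given.
    """

    calibration: str | None = None
    gloss_index: str = "delta_L"
    tongue_mask: str | None = None
    roi_mask: str | None = None
    roi: dict = field(default_factory=dict)
    moisture_model: str | None = None
    recovery_criterion: float = 0.95
    mm_per_px: float | None = None
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.gloss_index not in _GLOSS_INDICES:
            raise InputError(
                f"gloss_index must be one of {_GLOSS_INDICES}, got {self.gloss_index!r}"
            )
        if not 0 < self.recovery_criterion <= 1:
            raise InputError("recovery_criterion must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise InputError(f"config {path!s} must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"config {path!s} has unknown keys: {sorted(unknown)}")
        return cls(**payload)
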