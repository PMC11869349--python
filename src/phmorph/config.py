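"""Run configuration: every tunable knob, serialisable to plain-text YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .pipeline import MeasureConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Whole-run configuration tying the pipeline and statistics together.

    Units are asserted, never inferred: ``units`` exists only so non-mm
    inputs are refused explicitly.
    """

    units: str = "mm"
    rim_band_mm: float = 1.0
    rim_augment: bool = False
    head_margin_mm: float = 0.5
    meta_band_near: float = 1.0   # x provisional HHD
    meta_band_far: float = 2.5    # x provisional HHD
    n_slices: int = 8
    apex_method: str = "sphere"
    circle_from_landmarks: bool = False
    snap_landmarks: bool = False
    snap_mm: float = 2.0
    t_method: str = "pooled"      # summary t-test default: pooled | welch
    lilliefors: bool = False      # corrected KS normality screen
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.units != "mm":
            raise ValueError("only millimetre inputs are supported")
        for name in ("rim_band_mm", "head_margin_mm", "snap_mm",
                     "meta_band_near", "meta_band_far"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.meta_band_near >= self.meta_band_far:
            raise ValueError("meta_band_near must be < meta_band_far")
        if self.t_method not in ("pooled", "welch"):
            raise ValueError("t_method must be 'pooled' or 'welch'")

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            rim_band_mm=self.rim_band_mm,
            rim_augment=self.rim_augment,
            head_margin_mm=self.head_margin_mm,
            meta_band=(self.meta_band_near, self.meta_band_far),
            n_slices=self.n_slices,
            apex_method=self.apex_method,
            circle_from_landmarks=self.circle_from_landmarks,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
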