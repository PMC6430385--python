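"""Run configuration: every pipeline threshold in one overridable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ThermoscopeError


@dataclass
class RunConfig:
    """Defaults mirror the standard acute-ramp protocol and QC gates."""

    # respirometry
    trim_seconds: float = 60.0
    bin_seconds: float = 60.0
    r2_min_slope: float = 0.90
    saturation_min: float = 0.80
    saturation_reference: float | None = None
    # thermal window
    r2_min_window: float = 0.98
    min_span: int = 4
    rise_fraction: float = 0.25
    plateau_tol: float | None = None
    acclimation_temperature: float = 29.0
    # qPCR
    reference_genes: list[str] = field(default_factory=lambda: ["actb", "18s"])
    target_genes: list[str] | None = None
    efficiencies: dict[str, float] | None = None
    calibration: str = "all_samples"
    comparisons: list[list[str]] = field(
        default_factory=lambda: [
            ["heat_41C", "control_29C"],
            ["cold_17C", "control_29C"],
        ]
    )
    pooling: dict[str, list[str]] | None = None
    replicate_sd_warn: float = 0.5
    # simulation
    seed: int = 0
    n_per_arm: int = 8

    def validate(self) -> "RunConfig":
        if not (0 <= self.r2_min_slope <= 1 and 0 <= self.r2_min_window <= 1):
            raise ThermoscopeError("R^2 thresholds must lie in [0, 1]")
        if not (0 <= self.saturation_min <= 1):
            raise ThermoscopeError("saturation_min must lie in [0, 1]")
        if self.trim_seconds < 0 or self.min_span < 2:
            raise ThermoscopeError("trim_seconds >= 0 and min_span >= 2 required")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ThermoscopeError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw).validate()
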