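"""Experiment configuration: stage probabilities, durations, thresholds, strategy knobs.

An attempt at one cell decomposes into Bernoulli stage outcomes — neuron
hunting, gigasealing, break-in — whose product is the end-to-end whole-cell
success rate.  The defaults (0.9 x 0.725 x 0.8 = 0.522) reproduce the 52.2%
aggregate rate of a well-tuned two-pipette robot; ``whole_cell_success`` is a
single-probability shortcut that overrides the per-stage decomposition.

Stage durations are sampled from truncated normals (non-negative); the default
means are sanity anchors that put simulated time-to-pair in the ~10-15 min
range — they are configuration, not assertions about any particular rig.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .rig_model import ConnectivityProtocol, DetectionThresholds, QCRule

__all__ = ["StageDuration", "StageDurations", "ExperimentConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unsupported experiment configuration."""


class StageDuration(BaseModel):
    """Truncated-normal duration (seconds); sd 0 makes the stage deterministic."""

    mean_s: float = Field(ge=0)
    sd_s: float = Field(default=0.0, ge=0)


class StageDurations(BaseModel):
    pipette_finding: StageDuration = StageDuration(mean_s=40.0, sd_s=10.0)
    neuron_hunting: StageDuration = StageDuration(mean_s=90.0, sd_s=30.0)
    gigaseal: StageDuration = StageDuration(mean_s=100.0, sd_s=40.0)
    break_in: StageDuration = StageDuration(mean_s=30.0, sd_s=10.0)
    connectivity_test: StageDuration = StageDuration(mean_s=120.0, sd_s=20.0)
    cleaning: StageDuration = StageDuration(mean_s=60.0, sd_s=10.0)


class ExperimentConfig(BaseModel):
    """Everything a simulated patching session needs besides the slice itself."""

    n_pipettes: int = Field(default=2, ge=2)
    hunt_success: float = Field(default=0.9, ge=0, le=1)
    seal_success: float = Field(default=0.725, ge=0, le=1)
    breakin_success: float = Field(default=0.8, ge=0, le=1)
    whole_cell_success: Optional[float] = Field(default=None, ge=0, le=1)
    detect_prob: float = Field(default=1.0, ge=0, le=1)
    durations: StageDurations = StageDurations()
    pair_distance_min_um: float = Field(default=0.0, ge=0)
    pair_distance_max_um: Optional[float] = Field(default=None, gt=0)
    max_duration_s: float = Field(default=4 * 3600.0, gt=0)
    pipette_homes: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 100.0, 0.0),
        (200.0, 100.0, 0.0),
    )
    thresholds: DetectionThresholds = DetectionThresholds()
    qc: QCRule = QCRule()
    connectivity: ConnectivityProtocol = ConnectivityProtocol()

    @model_validator(mode="after")
    def _check_ranges(self) -> "ExperimentConfig":
        if (
            self.pair_distance_max_um is not None
            and self.pair_distance_max_um <= self.pair_distance_min_um
        ):
            raise ValueError("pair_distance_max_um must exceed pair_distance_min_um")
        return self

    @property
    def whole_cell_probability(self) -> float:
        """End-to-end per-attempt whole-cell success probability."""
        if self.whole_cell_success is not None:
            return self.whole_cell_success
        return self.hunt_success * self.seal_success * self.breakin_success

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load from a JSON or YAML file (schema-validated)."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data or {})

    def config_hash(self) -> str:
        """Short stable digest for provenance logging of runs."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
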