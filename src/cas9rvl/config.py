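"""Validated run configuration (YAML) for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError
from .library import TargetSpec, make_target_spec
from .simulate import KineticParams, PenaltyProfile, default_penalty_profile


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TargetBlock(_Strict):
    protospacer: str = "ACGCATGCACCTAGCGATCT"
    flank5: str = "TCGATG"
    flank3: str = "CATGCA"
    pam_n: str = "A"
    doping_rate: float = 0.10
    doping_overrides: dict[int, float] = Field(default_factory=dict)

    def build(self) -> TargetSpec:
        return make_target_spec(
            self.protospacer,
            flank5=self.flank5,
            flank3=self.flank3,
            pam_n=self.pam_n,
            doping_rate=self.doping_rate,
            doping_overrides=self.doping_overrides,
        )


class KineticsBlock(_Strict):
    burst_fraction: float = 0.3
    k_fast: float = 0.5
    k_slow: float = 0.01

    def build(self, timepoints: list[float]) -> KineticParams:
        return KineticParams(
            self.burst_fraction, self.k_fast, self.k_slow, tuple(timepoints)
        )


class SpikeInBlock(_Strict):
    fraction: float = 0.05
    n_species: int = 40
    protospacer: str = "GTTCGAAGGCTTAACCGTGA"
    flank5: str = "AGGTCA"
    flank3: str = "TTGACC"
    pam_n: str = "C"

    def build_spec(self) -> TargetSpec:
        return make_target_spec(
            self.protospacer, flank5=self.flank5, flank3=self.flank3, pam_n=self.pam_n
        )


class SimulationBlock(_Strict):
    n_species: int = 400
    depth: int = 1_000_000
    timepoints: list[float] = Field(default_factory=lambda: [15.0, 60.0, 180.0])
    seed: int = 0
    sampling: Literal["multinomial", "expected"] = "multinomial"
    kinetics: KineticsBlock = Field(default_factory=KineticsBlock)
    spike_in: SpikeInBlock | None = Field(default_factory=SpikeInBlock)
    profile: str | dict[str, float] = "default"
    sequencing_error: float = 0.0

    @field_validator("timepoints")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if v != sorted(v) or any(t < 0 for t in v):
            raise ValueError("timepoints must be non-negative and increasing")
        return v

    def build_profile(self, spec: TargetSpec) -> PenaltyProfile:
        profile = default_penalty_profile(spec)
        if self.profile == "default":
            return profile
        if isinstance(self.profile, str):
            raise ValidationError(f"unknown profile preset {self.profile!r}")
        for key, value in self.profile.items():
            pos_s, base = key.split(":")
            profile.penalty[(int(pos_s), base)] = float(value)
        return PenaltyProfile(profile.penalty, profile.flank_modifier, profile.max_enhancement)


class AnalysisBlock(_Strict):
    reference: Literal["mismatch47", "spikein"] = "mismatch47"
    min_count: int = 50
    alpha: float = 0.05
    n_min: int = 1
    pseudocount: float = 0.0
    timepoint: float | None = None
    timecourse_variants: list[str] = Field(default_factory=lambda: ["WT"])

    @property
    def reference_mode(self) -> str:
        return "mismatch_class" if self.reference == "mismatch47" else "spike_in"


class RunConfig(_Strict):
    target: TargetBlock = Field(default_factory=TargetBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic error message already carries field paths
        raise ValidationError(f"invalid configuration {path}: {exc}") from exc
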