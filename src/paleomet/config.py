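"""Strictly-validated run configuration (YAML/JSON) for the pipeline.

Unknown keys are rejected rather than silently ignored, so a typo in a
config file never falls back to a default.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .allometry import DEFAULT_CLADE_EXPONENTS

__all__ = [
    "FossilConfig",
    "HemodynamicsConfig",
    "AllometryConfig",
    "PEMConfig",
    "InferenceConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FossilConfig(_Strict):
    """One fossil: graft position plus either a foramen area or a flow."""

    label: str
    attach: str
    attach_time: Optional[float] = None
    stem_length: float = Field(default=0.0, ge=0.0)
    tip_age: Optional[float] = Field(default=None, ge=0.0)
    foramen_area_mm2: Optional[float] = Field(default=None, gt=0.0)
    lumen_fraction: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    q_ml_s: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _one_flow_source(self) -> "FossilConfig":
        if (self.foramen_area_mm2 is None) == (self.q_ml_s is None):
            raise ValueError(
                f"fossil {self.label!r}: give exactly one of foramen_area_mm2 "
                "or q_ml_s"
            )
        return self


class HemodynamicsConfig(_Strict):
    lumen_fraction: float = Field(default=0.20, gt=0.0, le=1.0)


class AllometryConfig(_Strict):
    clade_exponents: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CLADE_EXPONENTS)
    )
    b_override: Optional[float] = Field(default=None, gt=0.0, lt=2.0)

    @field_validator("clade_exponents")
    @classmethod
    def _exponent_range(cls, v: dict[str, float]) -> dict[str, float]:
        for clade, e in v.items():
            if not (0.0 < e < 2.0):
                raise ValueError(f"exponent for {clade!r} outside (0, 2)")
        return v


class PEMConfig(_Strict):
    a: float = Field(default=0.0, ge=0.0, lt=1.0)
    psi: float = Field(default=1.0, gt=0.0)
    grid_search_a: bool = False


class InferenceConfig(_Strict):
    interval: Literal["confidence", "prediction"] = "confidence"
    loocv_test: Literal["t", "wilcoxon"] = "t"
    level: float = Field(default=0.95, gt=0.0, lt=1.0)


class RunConfig(_Strict):
    species_csv: Path
    tree_newick: Path
    fossils: list[FossilConfig] = Field(default_factory=list)
    hemodynamics: HemodynamicsConfig = Field(default_factory=HemodynamicsConfig)
    allometry: AllometryConfig = Field(default_factory=AllometryConfig)
    pem: PEMConfig = Field(default_factory=PEMConfig)
    inference: InferenceConfig = Field(default_factory=InferenceConfig)
    output_dir: Path = Path("results")
    seed: int = 0

    @model_validator(mode="after")
    def _unique_fossil_labels(self) -> "RunConfig":
        labels = [f.label for f in self.fossils]
        if len(set(labels)) != len(labels):
            raise ValueError("fossil labels must be unique")
        return self

    def check_files(self) -> None:
        for p in (self.species_csv, self.tree_newick):
            if not Path(p).is_file():
                raise FileNotFoundError(f"input file not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; relative paths resolve against its directory."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = RunConfig.model_validate(raw)
    base = path.parent
    updates = {}
    for key in ("species_csv", "tree_newick", "output_dir"):
        p = getattr(cfg, key)
        if not p.is_absolute():
            updates[key] = (base / p).resolve()
    cfg = cfg.model_copy(update=updates)
    cfg.check_files()
    return cfg
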