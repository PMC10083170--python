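"""Run configuration: strict YAML schema whose defaults reproduce the
published thresholds and gene sets, so a bare invocation runs the shipped
algorithm unchanged."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .panel import FBCL2, FBCL6, SubtypeDefinition
from .records import FilterThresholds, SequencingMode


class ThresholdsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_mapping_quality: float = 30.0
    max_pop_af: float = 0.001
    min_vaf: float = 0.05
    min_depth: int = 10
    max_sift: float = 0.05
    min_polyphen: float = 0.447
    min_cadd: float = 4.0
    dbsnp_requires_cosmic: bool = True
    missense_scores_fail_open: bool = False

    def build(self) -> FilterThresholds:
        return FilterThresholds(**self.model_dump())


class RunConfig(BaseModel):
    """Configuration of a classification run.  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    mode: SequencingMode = SequencingMode.WES_WGS
    thresholds: ThresholdsConfig = Field(default_factory=ThresholdsConfig)
    policy: str = "nos_on_tie"
    definitions_path: Optional[Path] = None
    out_dir: Path = Path(".")
    verbosity: int = 1
    legacy20: bool = False
    myd88_l265p_only: bool = False
    seed: int = 0

    @field_validator("policy")
    @classmethod
    def _known_policy(cls, v: str) -> str:
        from .estimator import TIE_BREAK_POLICIES

        if v not in TIE_BREAK_POLICIES:
            raise ValueError(
                f"unknown policy {v!r}; expected one of {TIE_BREAK_POLICIES}")
        return v


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def load_definitions(path: str | Path) -> tuple[SubtypeDefinition, ...]:
    """Load subtype-definition overrides from YAML/JSON.

    Layout: a mapping of subtype name to ``{mutation_genes: [...],
    rearrangements: [FBCL2|FBCL6, ...]}``.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    defs = []
    for name, spec in data.items():
        if not isinstance(spec, dict) or set(spec) - {"mutation_genes",
                                                      "rearrangements"}:
            raise ValueError(
                f"definition {name!r} must map to mutation_genes/rearrangements")
        genes = frozenset(str(g).upper() for g in spec.get("mutation_genes", []))
        rearr = frozenset(str(r).upper() for r in spec.get("rearrangements", []))
        if rearr - {FBCL2, FBCL6}:
            raise ValueError(
                f"definition {name!r}: rearrangements must be FBCL2/FBCL6")
        defs.append(SubtypeDefinition(str(name), genes, rearr))
    if not defs:
        raise ValueError(f"no definitions found in {path}")
    return tuple(defs)
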