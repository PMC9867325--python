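"""Pipeline configuration: one YAML file carrying every tunable.

Unknown keys are rejected so a typo cannot silently fall back to a
default.  Bare defaults reproduce the published matching rules
(85% identity, 90% query coverage, >90% typing identity, leader-proximal
cutoff p <= 0.20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .arrays import ArrayFinderParams
from .matching import MatchParams


@dataclass
class RecencyCutoffs:
    proximal_max: float = 0.20
    distal_min: float = 2.0 / 3.0


@dataclass
class PipelineConfig:
    seed: int = 0
    genome: str | None = None
    targets: str | None = None
    features: str | None = None
    proteins: str | None = None  # directory of <category>.faa files
    outdir: str = "crisprtrace_out"
    array_finder: ArrayFinderParams = field(default_factory=ArrayFinderParams)
    match: MatchParams = field(default_factory=MatchParams)
    typing_threshold: float = 0.90
    recency: RecencyCutoffs = field(default_factory=RecencyCutoffs)
    pam_window: int = 3
    pam_agreement: float = 0.75

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_type, data, where):
            if not isinstance(data, dict):
                raise ValueError(f"config section {where!r} must be a mapping")
            allowed = {f.name: f for f in fields(dc_type)}
            unknown = set(data) - set(allowed)
            if unknown:
                raise ValueError(
                    f"unknown config key(s) in {where!r}: {sorted(unknown)}"
                )
            kwargs = {}
            for name, value in data.items():
                f = allowed[name]
                if f.name == "array_finder":
                    value = build(ArrayFinderParams, value, "array_finder")
                elif f.name == "match":
                    value = build(MatchParams, value, "match")
                elif f.name == "recency":
                    value = build(RecencyCutoffs, value, "recency")
                kwargs[name] = value
            return dc_type(**kwargs)

        return build(cls, raw, "<root>")
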