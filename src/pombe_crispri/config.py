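"""Run configuration: every tunable constant with documented defaults.

A RunConfig round-trips losslessly through YAML, so a run can be reproduced
from the config it logs. CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from pombe_crispri.guides import ScoringRules


@dataclass
class RunConfig:
    """Resolved configuration of a design/quantify run."""

    scoring: ScoringRules = field(default_factory=ScoringRules)
    spacer_length: int = 20
    upstream: int = 200
    downstream: int = 300
    tm_method: str = "wallace"  # wallace | nearest_neighbor
    qpcr_efficiency: float = 2.0
    top_overhang: str = "CACC"
    bottom_overhang: str = "AAAC"
    seed: int = 0
    verbosity: int = 1

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scoring" in data and data["scoring"] is not None:
            data["scoring"] = ScoringRules(**data["scoring"])
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())
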