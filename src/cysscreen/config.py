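"""Pipeline configuration shared by the library and the CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Effective screening configuration; echoed into every output header."""

    length_limit: int = 150
    require_stop: bool = True
    all_starts: bool = False
    motif_db_path: Optional[str] = None
    predictor: str = "builtin"
    min_cys: int = 4
    mature_region_rule: bool = True
    seed: int = 0
    threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.length_limit < 1:
            raise ValueError("length_limit must be >= 1")
        if self.min_cys < 0:
            raise ValueError("min_cys must be >= 0")
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0.5, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
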