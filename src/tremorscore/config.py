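"""Pipeline configuration bundle and its canonical hash.

A control reference is only meaningful relative to the exact spectral and
scoring settings it was computed under (window length, band, smoothing,
resampling factors).  The pipeline therefore hashes the canonical JSON of
those settings and refuses to mix scores across different hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .index import IndexConfig
from .spectral import SpectralConfig

__all__ = ["PipelineConfig", "config_hash"]


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def config_hash(spectral: SpectralConfig, index: IndexConfig) -> str:
    """Stable short hash of the analysis-relevant configuration."""
    payload = _canonical_json(
        {"spectral": spectral.to_dict(), "index": index.to_dict()}
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineConfig:
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    index: IndexConfig = field(default_factory=IndexConfig)
    dialect: str = "phone"
    seed: int = 0

    @property
    def hash(self) -> str:
        return config_hash(self.spectral, self.index)

    def to_dict(self) -> dict:
        return {
            "spectral": self.spectral.to_dict(),
            "index": self.index.to_dict(),
            "dialect": self.dialect,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            spectral=SpectralConfig.from_dict(d.get("spectral", {})),
            index=IndexConfig.from_dict(d.get("index", {})),
            dialect=d.get("dialect", "phone"),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
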