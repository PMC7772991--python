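"""Pipeline configuration: the thresholds every stage shares."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and options shared across the pipeline.

    ``multiplier`` is the positivity rule (signal must exceed multiplier x
    background); ``dec_fraction`` scales the deconvoluted-signal threshold;
    ``consistency_tolerance`` the forward-consistency check;
    ``replicate_cv_limit`` flags noisy replicate groups; ``weak_link_floor``
    zeroes negligible matrix entries; ``subtract_before_positivity``
    controls whether control subtraction precedes the positivity rule.
    """

    multiplier: float = 2.5
    dec_fraction: float = 0.5
    consistency_tolerance: float = 0.5
    replicate_cv_limit: float = 0.25
    weak_link_floor: float = 0.01
    dialect: str = "tsv"
    seed: int = 0
    subtract_before_positivity: bool = True

    def __post_init__(self) -> None:
        for name in ("multiplier", "dec_fraction", "consistency_tolerance",
                     "replicate_cv_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weak_link_floor < 0:
            raise ValueError("weak_link_floor must be non-negative")
        if self.dialect not in ("tsv", "genepix_like"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**(data or {}))

    def digest(self) -> str:
        """Short stable hash of the configuration, for report headers."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
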