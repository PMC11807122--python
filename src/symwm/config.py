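"""Pipeline configuration: seeds, stage parameters, serialization."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """End-to-end configuration; every stochastic stage derives its seed
    from ``seed`` unless an explicit per-stage seed is given."""

    seed: int = 0
    n_subjects: int = 20
    n_blocks: int = 4                  # blocks of 72 trials per subject
    stimulus_seed: int | None = None
    encoder_settings: dict = field(default_factory=dict)
    sci_threshold: float = 0.05
    cv_rule: str = "adaptive"
    glm_cutoff_hz: float = 0.03
    event_duration_s: float = 0.25
    fdr_alpha: float = 0.05
    posthoc_method: str = "tukey"
    power: dict = field(default_factory=lambda: {
        "m": 4, "f": 0.25, "rho": 0.5, "alpha": 0.05,
        "epsilon": 1.0, "target_power": 0.95})

    def stage_seed(self, stage: str, index: int = 0) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}:{index}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
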