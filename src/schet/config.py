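"""Pipeline configuration: every stage parameter with defaults, YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters.

    Defaults follow the study conventions: soft power 12 for the signed
    network, 150 exported edges, p/q thresholds of 0.05, and an HVG FDR
    of 0.1.
    """

    seed: int = 0
    # spike-in recognition
    spikein_prefixes: list[str] = field(default_factory=lambda: ["ERCC-"])
    spikein_ids: list[str] = field(default_factory=list)
    # normalization
    exclude_spikeins_from_size_factors: bool = True
    rescale_size_factors: bool = True
    # variability
    hvg_fdr: float = 0.1
    # error model / DE
    dropout_lambda: float = 0.1
    de_alpha: float = 0.05
    # subgroups
    n_clusters: int | None = None
    max_clusters: int = 8
    n_pca_components: int = 2
    # network
    soft_power: float = 12.0
    min_module_size: int = 30
    deep_split: int = 2
    n_top_edges: int = 150
    # preservation
    n_permutations: int = 200
    # cell cycle
    n_expression_bins: int = 25
    phase_score_threshold: float = 0.0
    # screening / enrichment
    screen_min_datasets: int = 2
    screen_q_threshold: float = 0.05
    enrichment_alpha: float = 0.05
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self) -> "PipelineConfig":
        if self.soft_power < 1:
            raise ConfigError(f"soft_power must be >= 1, got {self.soft_power}")
        if self.n_permutations < 10:
            raise ConfigError(
                f"n_permutations must be >= 10, got {self.n_permutations}"
            )
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be a fixed integer")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        for name in ("hvg_fdr", "de_alpha", "screen_q_threshold", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.n_expression_bins < 1:
            raise ConfigError("n_expression_bins must be >= 1")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash recorded in run logs so every number is traceable."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
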