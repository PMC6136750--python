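"""Run configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .classify import TierThresholds
from .errors import ConfigError
from .evidence_lr import CATEGORIES, DEFAULT_LEVELS


@dataclass
class RunConfig:
    """All tunable settings, serialised into every output's metadata."""

    seed: int = 17
    # MCMC
    burn_in: int = 20000
    n_samples: int = 1000
    prior_var: float = 100.0
    # stepwise selection
    penalties: tuple = (2, 3, 4, 5, 6, 7, 8)
    cv_folds: int = 5
    # training-set expansion
    min_negative: float = 5.0
    min_positive: float = 5.0
    merge_descending: bool = True
    # normalisation
    knn_k: int = 40
    impute_per_gene: bool = False
    # evidence / classification
    evidence_categories: tuple = CATEGORIES
    level_map: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    hotspot_level: str | None = "P-4"
    thresholds: TierThresholds = field(default_factory=TierThresholds)
    pci_level: float = 0.95
    prior_clip: tuple = (0.001, 0.999)

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_samples < 1:
            raise ConfigError("burn_in must be >= 0 and n_samples >= 1")
        unknown = set(self.evidence_categories) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown evidence categories: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        d["penalties"] = list(self.penalties)
        d["evidence_categories"] = list(self.evidence_categories)
        d["prior_clip"] = list(self.prior_clip)
        d["level_map"] = {k: list(v) for k, v in self.level_map.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = TierThresholds(**d["thresholds"])
        for key in ("penalties", "evidence_categories", "prior_clip"):
            if key in d:
                d[key] = tuple(d[key])
        if "level_map" in d:
            d["level_map"] = {k: tuple(v) for k, v in d["level_map"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
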