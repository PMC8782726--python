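"""Screening configuration: the cut-off theta, top-N and channel tunables."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

REPRESENTATIONS = ("embed1d", "pharm2d", "shape3d")


@dataclass
class ScreeningConfig:
    """All screening tunables.

    theta is the similarity cut-off of the hyper-space filter (default 0.75);
    scores below it, and exact matches (s = 1), are zeroed. ``top_n`` truncates
    the candidate list; None keeps every passing compound.
    """

    theta: float = 0.75
    top_n: int | None = None
    representation_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    aggregate_rule: str = "mean"          # mean | min | rank_mean
    ref_combine: str = "max"              # max | mean over the reference panel
    threshold_mode: str = "combined"      # combined | per_channel
    outlier_mad_k: float = 3.5
    seed: int = 0
    # per-representation hyperparameters
    radius: int = 1
    vector_size: int = 100
    window: int = 10
    min_count: int = 1
    epochs: int = 5
    fingerprint_size: int = 2048
    n_conformers: int = 10

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ConfigError(f"theta must lie in (0, 1), got {self.theta}")
        w = self.representation_weights
        if len(w) != 3 or any(x < 0 for x in w):
            raise ConfigError("representation_weights must be three non-negative reals")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ConfigError(f"representation_weights must sum to 1, got {sum(w)}")
        if self.aggregate_rule not in ("mean", "min", "rank_mean"):
            raise ConfigError(f"unknown aggregate_rule {self.aggregate_rule!r}")
        if self.ref_combine not in ("max", "mean"):
            raise ConfigError(f"unknown ref_combine {self.ref_combine!r}")
        if self.threshold_mode not in ("combined", "per_channel"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.outlier_mad_k <= 0:
            raise ConfigError(f"outlier_mad_k must be positive, got {self.outlier_mad_k}")
        if self.top_n is not None and self.top_n < 1:
            raise ConfigError(f"top_n must be positive, got {self.top_n}")
        if self.radius < 0:
            raise ConfigError(f"radius must be >= 0, got {self.radius}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["representation_weights"] = list(self.representation_weights)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScreeningConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "representation_weights" in data:
            data = dict(data)
            data["representation_weights"] = tuple(data["representation_weights"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreeningConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def with_overrides(self, **overrides) -> "ScreeningConfig":
        """New config with non-None overrides applied (flags > file > defaults)."""
        data = self.to_dict()
        for k, v in overrides.items():
            if v is not None:
                data[k] = v
        return ScreeningConfig.from_dict(data)
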