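"""Run configuration: YAML/JSON parsing with validated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .validation import DEFAULT_METRICS

__all__ = ["RunConfig", "parse_config"]

_MATCHING_METHODS = ("mahalanobis", "predicted_benefit")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    m_imputations: int = 5  # completed datasets per multiple imputation
    n_boot: int = 500  # bootstrap resamples for delta-C intervals
    matching_method: str = "mahalanobis"
    knot_policy: str = "percentile_10_50_90"
    metrics: list[str] = field(default_factory=lambda: list(DEFAULT_METRICS))
    output_dir: str = "results"

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed: must be a nonnegative integer")
        if self.m_imputations < 1:
            raise ConfigError("m_imputations: must be >= 1")
        if self.n_boot < 100:
            raise ConfigError("n_boot: must be >= 100")
        if self.matching_method not in _MATCHING_METHODS:
            raise ConfigError(
                f"matching_method: must be one of {_MATCHING_METHODS}"
            )
        unknown = set(self.metrics) - set(DEFAULT_METRICS)
        if unknown:
            raise ConfigError(f"metrics: unknown {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def parse_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration; missing keys take defaults,
    unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as e:
        raise ConfigError(str(e)) from e
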