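"""Single-file pipeline configuration.

One YAML file composes the cohort-generator, validity, intensity and
preprocessing settings plus paths and the seed.  Unknown keys are
rejected — a typo never silently falls back to a default — and the empty
document is a fully defaulted, valid configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metrics import IntensityConfig
from .pipeline import ProcessOptions
from .synthetic import CohortConfig
from .validity import ValidityConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    intensity: IntensityConfig = field(default_factory=IntensityConfig)
    hr_max_gap_minutes: int = 60
    movement_fraction_threshold: float = 0.10
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def process_options(self) -> ProcessOptions:
        return ProcessOptions(
            validity=self.validity, intensity=self.intensity,
            hr_max_gap_minutes=self.hr_max_gap_minutes,
            movement_fraction_threshold=self.movement_fraction_threshold)


def _build(cls, data: dict, context: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if key == "base_date" and isinstance(value, str):
            value = dt.date.fromisoformat(value)
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from None


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load the pipeline configuration from YAML, with optional overrides.

    ``overrides`` is a flat dict of top-level keys (e.g. ``{"seed": 7}``)
    applied after the file, used for CLI flags.
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}

    sections = {"cohort": CohortConfig, "validity": ValidityConfig,
                "intensity": IntensityConfig}
    cohort_pinned_seed = "rng_seed" in ((data.get("cohort") or {}))
    kwargs: dict = {}
    for name, cls in sections.items():
        sub = data.pop(name, {}) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build(cls, sub, name)
    cfg = _build(PipelineConfig, {**data, **kwargs}, "pipeline")
    # the seed threads through to the generator unless the cohort section
    # pinned its own
    if not cohort_pinned_seed:
        cfg = dataclasses.replace(
            cfg, cohort=dataclasses.replace(cfg.cohort, rng_seed=cfg.seed))
    return cfg
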