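"""YAML pipeline configuration: schema, defaults, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ValidationError
from .simulate import SyntheticConfig

__all__ = ["PipelineConfig", "load_config", "default_config_dict"]


@dataclass
class SimulateSection:
    n_subjects: int = 10
    trials_per_subject: int = 3
    jitter: float = 0.1
    base: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValidationError("n_subjects and trials_per_subject must be >= 1")
        if not 0 <= self.jitter < 0.5:
            raise ValidationError("jitter must lie in [0, 0.5)")
        self.base.validate()


@dataclass
class FilterSection:
    low_hz: float = 1.0
    high_hz: float = 500.0
    order: int = 5

    def validate(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError("need 0 < filter.low_hz < filter.high_hz")
        if self.order < 1:
            raise ValidationError("filter.order must be >= 1")


@dataclass
class FuzzySection:
    # breakpoints of the angle/oscillation membership functions
    angle: dict = field(default_factory=lambda: {
        "NF": [86.5, 89.0, 180.0, 180.0],
        "TF": [86.5, 87.75, 89.0],
        "F": [0.0, 0.0, 86.5, 89.0],
    })
    osc: dict = field(default_factory=lambda: {
        "Low": [0.0, 0.0, 0.4, 0.8],
        "High": [0.4, 0.8, 10.0, 10.0],
    })
    osc_window_s: float = 4.0

    def validate(self) -> None:
        if set(self.angle) != {"NF", "TF", "F"}:
            raise ValidationError("fuzzy.angle must define NF, TF and F terms")
        if set(self.osc) != {"Low", "High"}:
            raise ValidationError("fuzzy.osc must define Low and High terms")
        if self.osc_window_s <= 0:
            raise ValidationError("fuzzy.osc_window_s must be positive")


@dataclass
class FeaturesSection:
    channel: int | str = 1
    span_s: int = 3
    fi_moments: list[int] = field(default_factory=lambda: [2])
    wavelet: str = "db3"
    level: int = 12

    def validate(self) -> None:
        if self.channel not in (1, 2, "mean"):
            raise ValidationError("features.channel must be 1, 2 or 'mean'")
        if self.span_s < 1:
            raise ValidationError("features.span_s must be >= 1")
        if any(x not in (2, 3, 4, 5) for x in self.fi_moments):
            raise ValidationError("features.fi_moments entries must be in 2..5")
        if self.level < 1:
            raise ValidationError("features.level must be >= 1")


@dataclass
class ClassifySection:
    train_frac: float = 0.5

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValidationError("classify.train_frac must lie in (0, 1)")


@dataclass
class ReportSection:
    reference_feature: str = "spectro_std"
    dbi_spans: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])

    def validate(self) -> None:
        if any(s < 1 for s in self.dbi_spans):
            raise ValidationError("report.dbi_spans entries must be >= 1")


@dataclass
class PipelineConfig:
    simulate: SimulateSection = field(default_factory=SimulateSection)
    filter: FilterSection = field(default_factory=FilterSection)
    fuzzy: FuzzySection = field(default_factory=FuzzySection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    classify: ClassifySection = field(default_factory=ClassifySection)
    report: ReportSection = field(default_factory=ReportSection)

    def validate(self) -> None:
        for section in dataclasses.fields(self):
            getattr(self, section.name).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        if key == "base":
            kwargs[key] = _build(SyntheticConfig, value or {}, f"{path}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load, merge and validate a pipeline configuration."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: top level must be a mapping")
    if overrides:
        for key, value in overrides.items():
            data.setdefault(key, {}).update(value)
    sections = {
        "simulate": SimulateSection, "filter": FilterSection,
        "fuzzy": FuzzySection, "features": FeaturesSection,
        "classify": ClassifySection, "report": ReportSection,
    }
    unknown = set(data) - set(sections)
    if unknown:
        raise ValidationError(f"unknown top-level section(s) {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name) or {}, name)
              for name, cls in sections.items()}
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


def default_config_dict() -> dict:
    return PipelineConfig().to_dict()
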