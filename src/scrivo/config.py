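"""Pipeline configuration: a YAML-serializable bundle of every knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .scoring import ConfigurationError


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with validation.

    Defaults match the analysis as published: inclusive 70% confidence
    cleaning, 100 ms tract-gap threshold, per-grade scaling of the
    eye-tracking metrics, full-cohort drawing centers, two challenging
    levels, six 80/20 baseline splits and 5x3 nested CV.
    """

    # paths
    input_dir: str | None = None
    out_dir: str = "reports"
    # simulation
    simulate: bool = True
    n_subjects: int = 53
    effect_scale: float = 1.0
    # dialect overrides (column names)
    dialect: dict = field(default_factory=dict)
    # cleaning / features
    min_confidence: float = 0.70
    tract_gap_s: float = 0.100
    scaling_scope: str = "eye"  # "eye" | "all" | "none"
    cohort_center_mode: str = "full"  # "full" | "train"
    n_challenging_levels: int = 2
    # modeling
    feature_sets: tuple = ("game", "eye", "drawing", "game_and_drawing", "all")
    n_repeats: int = 6
    test_frac: float = 0.2
    outer_k: int = 5
    inner_k: int = 3
    grid: dict | None = None
    top_k_features: int | None = None
    selection_mode: str = "per_fold"  # "per_fold" | "global"
    make_plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigurationError("min_confidence must be in [0, 1]")
        if self.tract_gap_s <= 0:
            raise ConfigurationError("tract_gap_s must be positive")
        if self.scaling_scope not in ("eye", "all", "none"):
            raise ConfigurationError("scaling_scope must be 'eye', 'all' or 'none'")
        if self.cohort_center_mode not in ("full", "train"):
            raise ConfigurationError("cohort_center_mode must be 'full' or 'train'")
        if self.selection_mode not in ("per_fold", "global"):
            raise ConfigurationError("selection_mode must be 'per_fold' or 'global'")
        if not 0.0 < self.test_frac < 1.0:
            raise ConfigurationError("test_frac must be in (0, 1)")
        if self.outer_k < 2 or self.inner_k < 2:
            raise ConfigurationError("outer_k and inner_k must be >= 2")
        if not self.simulate and not self.input_dir:
            raise ConfigurationError("input_dir required when simulate is off")
        unknown = [s for s in self.feature_sets if s not in
                   ("game", "eye", "drawing", "game_and_drawing", "all")]
        if unknown:
            raise ConfigurationError(f"unknown feature set(s) {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "feature_sets" in data:
            data["feature_sets"] = tuple(data["feature_sets"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["feature_sets"] = list(d["feature_sets"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
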