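"""Run configuration: training hyperparameters, augmentation, decisions.

Defaults carry the published training recipe: SGD with momentum, initial
learning rate 0.01, batch size 64, at most 333 epochs with early stopping
after 55 epochs without validation improvement. The momentum value itself
is not part of the recipe; 0.937, the family-standard default, is used
and exposed here.
"""

from __future__ import annotations

import difflib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .geometry import DecisionConfig

OPTIMIZERS = ("SGD", "Adam", "AdamW", "NAdam")


class ConfigError(ValueError):
    """Unknown key or bad value in a configuration file."""


@dataclass
class TrainingConfig:
    optimizer: str = "SGD"
    momentum: float = 0.937
    lr0: float = 0.01
    lrf: float = 0.1           # final lr fraction (cosine schedule)
    weight_decay: float = 0.0005
    batch: int = 64
    epochs: int = 333
    patience: int = 55
    imgsz: int = 640
    warmup_epochs: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ConfigError(
                f"optimizer must be one of {OPTIMIZERS}, got {self.optimizer!r}"
            )
        if self.lr0 <= 0:
            raise ConfigError("lr0 must be > 0")
        if not 0 < self.patience < self.epochs:
            raise ConfigError("patience must lie in (0, epochs)")
        if self.imgsz % 32:
            raise ConfigError("imgsz must be a multiple of 32")


@dataclass
class AugmentationConfig:
    crop_fraction: float = 1.0
    degrees: float = 0.0
    erasing: float = 0.4
    fliplr: float = 0.5
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    mosaic: float = 0.5
    scale: float = 0.2

    def __post_init__(self) -> None:
        for name in ("erasing", "fliplr", "mosaic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} is a probability, got {v}")


@dataclass
class RunConfig:
    """Everything a run needs, merged from defaults, file and overrides."""

    training: TrainingConfig = field(default_factory=TrainingConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    arch: str = "yolov11n_plus"
    num_classes: int = 2
    conf_threshold: float = 0.25

    def to_dict(self) -> dict:
        return {
            "arch": self.arch,
            "num_classes": self.num_classes,
            "conf_threshold": self.conf_threshold,
            "training": asdict(self.training),
            "augmentation": asdict(self.augmentation),
            "decision": asdict(self.decision),
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "training": TrainingConfig,
    "augmentation": AugmentationConfig,
    "decision": DecisionConfig,
}
_TOP_KEYS = {"arch", "num_classes", "conf_threshold", *_SECTIONS}


def _check_keys(given: dict, valid: set[str], where: str) -> None:
    for key in given:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(
                f"unknown key {key!r} in {where} (valid: {sorted(valid)}){suffix}"
            )


def load_config(
    path: Optional[str | Path] = None, overrides: Optional[dict] = None
) -> RunConfig:
    """Defaults <- YAML file <- overrides, with unknown keys rejected.

    Flat override keys may use dotted section paths ("training.lr0").
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        data = raw
    _check_keys(data, _TOP_KEYS, "config file")
    merged: dict[str, dict] = {name: dict(data.get(name, {})) for name in _SECTIONS}
    for name, cls in _SECTIONS.items():
        valid = {f.name for f in fields(cls)}
        _check_keys(merged[name], valid, f"section {name!r}")
    top = {k: data[k] for k in data if k not in _SECTIONS}
    for key, value in (overrides or {}).items():
        if "." in key:
            section, sub = key.split(".", 1)
            if section not in _SECTIONS:
                raise ConfigError(f"unknown section {section!r} in override {key!r}")
            valid = {f.name for f in fields(_SECTIONS[section])}
            _check_keys({sub: value}, valid, f"section {section!r}")
            merged[section][sub] = value
        else:
            _check_keys({key: value}, _TOP_KEYS, "overrides")
            top[key] = value
    try:
        return RunConfig(
            training=TrainingConfig(**merged["training"]),
            augmentation=AugmentationConfig(**merged["augmentation"]),
            decision=DecisionConfig(**merged["decision"]),
            **top,
        )
    except TypeError as exc:  # wrong value type reached a dataclass
        raise ConfigError(str(exc)) from exc
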