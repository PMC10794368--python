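"""Experiment configuration: YAML/flag parsing with strict validation.

A single global seed fans out to every stochastic component (data rendering,
weight init, shuffling), so runs are reproducible from the manifest alone.
Unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .data import SyntheticSpec
from .engine import TrainConfig
from .errors import ConfigurationError
from .losses import AlignmentLossConfig
from .vit import ViTConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class ModelSection(_Strict):
    image_size: int = 32
    patch_size: int = 8
    channels: int = 3
    embed_dim: int = 96
    depth: int = 4
    heads: int = 4
    mlp_ratio: float = 2.0
    dropout_rate: float = 0.0
    qkv_init_std: float = 0.15


class AlignmentSection(_Strict):
    distance: Literal["tv", "js", "hellinger", "bhattacharyya"] = "tv"
    lam: float = Field(default=1.0, alias="lambda", ge=0.0)
    reduction: Literal["mean", "sum"] = "mean"
    epsilon: float = Field(default=1e-8, gt=0.0, le=1e-3)
    blocks: Optional[list[int]] = None


class TrainSection(_Strict):
    epochs_per_stage: int = Field(default=10, ge=1)
    batch_size: int = Field(default=32, ge=1)
    optimizer: Literal["adamw", "adamax"] = "adamax"
    learning_rate: float = Field(default=5e-4, gt=0.0)
    strategy: Literal["finetuning", "freezing",
                      "attention_alignment"] = "attention_alignment"
    cosine_decay: bool = True


class DataSection(_Strict):
    source: str = "synthetic"  # "synthetic" or "folder:<path>"
    n_classes: int = Field(default=13, ge=1)
    image_size: int = 32
    train_per_class: int = Field(default=40, ge=1)
    test_per_class: int = Field(default=20, ge=1)
    noise_std: float = Field(default=0.05, ge=0.0)
    split_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)

    def folder_path(self) -> Optional[Path]:
        if self.source.startswith("folder:"):
            return Path(self.source.split(":", 1)[1])
        if self.source != "synthetic":
            raise ConfigurationError(
                f"data.source must be 'synthetic' or 'folder:<path>', "
                f"got {self.source!r}")
        return None


class SequenceSection(_Strict):
    steps: int = Field(default=3, ge=1)
    shuffle: bool = False


class ExperimentConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs"
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    alignment: AlignmentSection = Field(default_factory=AlignmentSection)
    data: DataSection = Field(default_factory=DataSection)
    sequence: SequenceSection = Field(default_factory=SequenceSection)

    # -- converters to runtime objects ---------------------------------------

    def vit_config(self) -> ViTConfig:
        return ViTConfig(**self.model.model_dump())

    def alignment_config(self) -> AlignmentLossConfig:
        d = self.alignment.model_dump()
        blocks = d.pop("blocks")
        return AlignmentLossConfig(
            blocks=tuple(blocks) if blocks is not None else None, **d)

    def train_config(self) -> TrainConfig:
        return TrainConfig(seed=self.seed, alignment=self.alignment_config(),
                           **self.train.model_dump())

    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(
            n_classes=self.data.n_classes, image_size=self.data.image_size,
            train_per_class=self.data.train_per_class,
            test_per_class=self.data.test_per_class,
            noise_std=self.data.noise_std, seed=self.seed)


def _nested_set(d: dict, dotted: str, value: Any) -> None:
    keys = dotted.split(".")
    for k in keys[:-1]:
        d = d.setdefault(k, {})
    d[keys[-1]] = value


def parse_config(path: str | Path | None = None,
                 overrides: dict[str, Any] | None = None) -> ExperimentConfig:
    """Build a validated config from an optional YAML file plus overrides.

    Overrides use dotted key paths (``train.strategy``) and take precedence
    over file values. A schema violation raises ``ConfigurationError``
    naming the offending key.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        raw = loaded
    for dotted, value in (overrides or {}).items():
        if value is not None:
            _nested_set(raw, dotted, value)
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigurationError(
            f"invalid config at {loc!r}: {first['msg']}") from None


def write_manifest(cfg: ExperimentConfig, out_dir: str | Path) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.model_dump(by_alias=True),
                "seed": cfg.seed, "package_version": __version__}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
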