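"""Experiment configuration: validated blocks, YAML round-trip."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Block):
    source: Literal["synthetic", "manifest"] = "synthetic"
    n_per_class: int = 200
    sequences: bool = False
    seed: int = 0
    manifest: Optional[str] = None


class EnvConfig(_Block):
    image_size: int = 224
    patch_size: int = 64
    stride: int = 32
    t_max: int = 16
    gamma: float = 0.99
    pos_frequencies: int = 2


class AgentsConfig(_Block):
    spatial_backbone: Literal["small-cnn", "resnet50-style"] = "small-cnn"
    temporal_backbone: Literal["gru", "lstm"] = "gru"


class FusionConfig(_Block):
    rule: Literal["vdn-sum", "fixed-average", "attention", "concat-head"] = "vdn-sum"


class TrainBlock(_Block):
    episodes: int = 3000
    learning_rate: float = 1e-4
    batch_size: int = 32
    replay_capacity: int = 10_000
    warmup_transitions: int = 200
    target_sync: int = 200
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_frac: float = 0.6
    train_every: int = 4
    tau: float = 1.0
    seed: int = 0


class EvalConfig(_Block):
    k_folds: int = 5
    prevalence: float = 0.20
    dca_min: float = 0.01
    dca_max: float = 0.30
    dca_step: float = 0.01
    positive_class: int = 1
    variants: list[str] = ["vdn-sum"]  # fusion rules compared by crossval


class ExperimentConfig(_Block):
    data: DataConfig = DataConfig()
    env: EnvConfig = EnvConfig()
    agents: AgentsConfig = AgentsConfig()
    fusion: FusionConfig = FusionConfig()
    train: TrainBlock = TrainBlock()
    eval: EvalConfig = EvalConfig()


def load_config(path) -> ExperimentConfig:
    """Parse a YAML experiment config; unknown keys are rejected with their path."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> ExperimentConfig:
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(part) for part in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid config ({locs})") from exc


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
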