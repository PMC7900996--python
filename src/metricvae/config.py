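"""Run configuration: one YAML-serializable object per training run.

Every reference hyperparameter appears exactly once as a default here or
in the dataclass it nests: latent 50, 3x384 bidirectional GRU, 900-dim
embedding, Adam lr 0.001, alpha1 = alpha3 = 0.75, alpha2 annealed
1.25 -> 0.75 by 0.1/epoch, metric coefficient 0.1, neighborhood fraction
0.25, k = 10 evaluation neighbors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backbone import ModelConfig
from .metric import MetricConfig
from .tcvae import AlphaSchedule

MODES = ("vae", "joint", "metric")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "metric"
    model: ModelConfig = field(default_factory=ModelConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    schedule: AlphaSchedule = field(default_factory=AlphaSchedule)
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    max_len: int = 64          # SMILES default; grammar-rule sequences use 12
    tokenizer: str = "smiles"  # or "whitespace"
    test_fraction: float = 0.2
    val_fraction: float = 0.0  # reserved from the training share when evaluating
    joint_gamma_weight: float = 0.1
    eval_k: int = 10
    eval_centers: int = 1000
    sequence_file: str | None = None
    property_file: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs >= 1 and batch_size >= 2 required")
        if self.max_len < 1:
            raise ValueError("max_len must be positive")


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    model = ModelConfig(**d.pop("model", {}))
    metric = d.pop("metric", {})
    if isinstance(metric, dict):
        metric = MetricConfig(**metric)
    schedule = d.pop("schedule", {})
    if isinstance(schedule, dict):
        schedule = AlphaSchedule(**schedule)
    return RunConfig(model=model, metric=metric, schedule=schedule, **d)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
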