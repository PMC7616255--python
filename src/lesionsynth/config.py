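"""YAML-backed run configuration with strict schema validation.

Unknown keys are rejected (typos surface immediately), defaults follow the
training protocol the networks were designed around (64³ cubes, learning
rate 5e-5, gradient-penalty weight 10), and every pipeline run writes its
fully-resolved config next to its outputs for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .losses import LossWeights
from .model import NetworkConfig
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NetworkSection(_Strict):
    side: int = 64
    base_channels: int = 16
    n_levels: int = 4
    latent_dim: int = 128
    leaky_slope: float = 0.2
    condition_dim: int = 1
    embed_hidden: int = 32

    def build(self) -> NetworkConfig:
        return NetworkConfig(**self.model_dump())


class WeightsSection(_Strict):
    w_rec: float = 1.0
    w_kl: float = 0.1
    w_adv: float = 1e-2
    gp_lambda: float = 10.0

    def build(self) -> LossWeights:
        return LossWeights(**self.model_dump())


class TrainingSection(_Strict):
    learning_rate: float = 5e-5
    batch_size: int = 13
    epochs: int = 1000
    critic_steps: int = 5
    seed: int = 0
    weights: WeightsSection = Field(default_factory=WeightsSection)

    @field_validator("learning_rate")
    @classmethod
    def _lr_positive(cls, v):
        if v <= 0:
            raise ValueError("learning_rate must be positive")
        return v

    def build(self, stage: str) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            critic_steps=self.critic_steps,
            seed=self.seed,
            weights=self.weights.build(),
            stage=stage,
        )


class SynthesisSection(_Strict):
    n: int = 100
    threshold: float = 0.5
    condition_low: float = 0.3
    condition_high: float = 0.8
    keep_largest: bool = True
    max_retries: int = 5


class PhantomSection(_Strict):
    n: int = 200
    side: int = 64
    volume_min: int = 500
    volume_max: int = 8000
    n_lobes: int = 3
    texture_contrast: float = 0.35
    background_smoothness: float = 4.0


class RunConfig(_Strict):
    network: NetworkSection = Field(default_factory=NetworkSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    synthesis: SynthesisSection = Field(default_factory=SynthesisSection)
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    data_dir: str | None = None
    out_dir: str = "runs"
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys raise with their name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
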