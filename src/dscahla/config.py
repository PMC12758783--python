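"""Configuration trees for the model, training protocol and runs.

Every unstated hyperparameter of the architecture is pinned here with its
default, so a run's resolved config fully determines the model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class EmbeddingConfig:
    provider: str = "fallback-hash"   # or "esmc-600m"
    d_plm: int = 32                   # fallback table width; 1152 for the real adapter
    d_plm_proj: int = 64
    use_plm: bool = True              # ablation: drop the PLM block entirely
    use_context: bool = True          # ablation: drop the context-enhanced one-hot
    l_pep: int = 32                   # standardized peptide length
    l_chain: int = 100                # per-chain standardized length (alpha + beta = 200)


@dataclass
class BackboneConfig:
    d_model: int = 64
    n_layers: int = 3
    n_heads: int = 4
    ffn_mult: int = 4
    dropout: float = 0.1
    kernel_pep: int = 9               # one binding-core window per convolution window
    kernel_hla: int = 5               # pocket-scale receptive field
    l_loc: int = 24                   # shared local length = 32 - 9 + 1 peptide windows


@dataclass
class DscaConfig:
    mode: str = "dual"                # "dual" or "conventional" (single-stream ablation)
    d_attn: int | None = None         # defaults to d_model


@dataclass
class HeadConfig:
    dropout: float = 0.1
    threshold: float = 0.5            # classification threshold tau


@dataclass
class TrainConfig:
    """The training protocol: Adadelta, early stopping, 5-fold CV."""

    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    rho: float = 0.9
    eps: float = 1e-2
    early_stop_patience: int = 7
    n_folds: int = 5
    max_epochs: int = 30
    batch_size: int = 32
    grad_clip: float = 0.5
    warmup_steps: int = 300           # linear learning-rate warmup
    lr_decay: float = 0.7             # stepwise decay factor ...
    lr_decay_start: int = 4           # ... applied from this epoch on ...
    lr_decay_every: int = 2           # ... every this many epochs
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "weight_decay", "early_stop_patience",
                     "n_folds", "max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TrainConfig.{name} must be positive")


@dataclass
class ModelConfig:
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    dsca: DscaConfig = field(default_factory=DscaConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    seed: int = 0

    @property
    def l_hla(self) -> int:
        return 2 * self.embedding.l_chain

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, tree: dict) -> "ModelConfig":
        kwargs = {}
        for f, sub in (("embedding", EmbeddingConfig), ("backbone", BackboneConfig),
                       ("dsca", DscaConfig), ("head", HeadConfig)):
            if f in tree:
                kwargs[f] = sub(**tree[f])
        if "seed" in tree:
            kwargs["seed"] = tree["seed"]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def tiny_config(seed: int = 0) -> ModelConfig:
    """Desk-scale configuration used throughout the tests and examples."""
    return ModelConfig(seed=seed)


def full_config(seed: int = 0) -> ModelConfig:
    """Larger configuration for real training runs."""
    cfg = ModelConfig(seed=seed)
    cfg.embedding.d_plm_proj = 256
    cfg.backbone.d_model = 256
    return cfg
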