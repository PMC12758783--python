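import numpy as np
import pytest

from dscahla import datasets
from dscahla.config import (
    BackboneConfig,
    DscaConfig,
    EmbeddingConfig,
    HeadConfig,
    ModelConfig,
)


def small_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """A miniature but fully wired model for fast unit tests."""
    cfg = ModelConfig(
        embedding=EmbeddingConfig(d_plm=8, d_plm_proj=8, l_pep=32, l_chain=30),
        backbone=BackboneConfig(d_model=16, n_layers=1, n_heads=2, ffn_mult=2,
                                dropout=0.0),
        dsca=DscaConfig(),
        head=HeadConfig(dropout=0.0),
        seed=seed,
    )
    for key, value in overrides.items():
        section, name = key.split(".")
        setattr(getattr(cfg, section), name, value)
    return cfg


@pytest.fixture(scope="session")
def tiny_world():
    world = datasets.generate_world(3, 2, seed=5)
    pairs = datasets.sample_dataset(world, 12, 5, seed=6)
    return world, pairs


@pytest.fixture(scope="session")
def recovery_results():
    """The three-seed parameter-recovery study (shared by the acceptance tests).

    This is the expensive fixture of the suite: it trains the tiny model on
    the synthetic world once per seed.
    """
    from dscahla.recovery import run_recovery

    return [run_recovery(seed) for seed in (1, 2, 3)]
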