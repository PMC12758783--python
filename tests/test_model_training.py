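"""Prediction head, loss, and the training protocol."""

import numpy as np
import pytest

from dscahla import TrainConfig, training
from dscahla.model import Featurizer, PredictionHead, PresentationModel, bce_loss
from dscahla.nn import Tensor

from conftest import small_model_config


def test_pool_and_concat_constant_and_length():
    head = PredictionHead(d_model=8, dropout=0.0, rng=np.random.default_rng(0))
    h = Tensor(np.full((2, 5, 8), 3.0, dtype=np.float32))
    pooled = head.pool_and_concat(h, h, np.ones((2, 5), bool), np.ones((2, 5), bool))
    assert pooled.shape == (2, 16)
    assert np.allclose(pooled.data, 3.0)


def test_pooling_is_order_free():
    head = PredictionHead(d_model=4, dropout=0.0, rng=np.random.default_rng(1))
    x = np.random.default_rng(2).normal(size=(1, 6, 4)).astype(np.float32)
    perm = x[:, ::-1].copy()
    mask = np.ones((1, 6), bool)
    a = head.pool_and_concat(Tensor(x), Tensor(x), mask, mask)
    b = head.pool_and_concat(Tensor(perm), Tensor(perm), mask, mask)
    assert np.allclose(a.data, b.data)


def test_predict_probability_zero_weights_gives_half():
    head = PredictionHead(d_model=8, dropout=0.0, rng=np.random.default_rng(3))
    for lin in (head.mlp1, head.mlp2, head.final):
        lin.weight.data[:] = 0
        lin.bias.data[:] = 0
    x = Tensor(np.random.default_rng(4).normal(size=(5, 16)).astype(np.float32))
    probs = head.predict_probability(x, np.random.default_rng(0))
    assert np.allclose(probs.data, 0.5)


def test_predict_probability_rejects_non_finite():
    head = PredictionHead(d_model=4, dropout=0.0, rng=np.random.default_rng(5))
    bad = Tensor(np.full((1, 8), np.nan, dtype=np.float32))
    with pytest.raises(ValueError):
        head.predict_probability(bad, np.random.default_rng(0))


def test_bce_printed_value_and_properties():
    probs = Tensor(np.array([0.5, 0.5], dtype=np.float32))
    assert abs(bce_loss(probs, [1, 0]).item() - np.log(2)) < 1e-6
    # permutation invariance
    p = Tensor(np.array([0.9, 0.2, 0.7], dtype=np.float32))
    a = bce_loss(p, [1, 0, 1]).item()
    p2 = Tensor(np.array([0.7, 0.9, 0.2], dtype=np.float32))
    assert abs(bce_loss(p2, [1, 1, 0]).item() - a) < 1e-6
    # perfect predictions drive the loss toward zero
    good = Tensor(np.array([1 - 1e-7, 1e-7], dtype=np.float32))
    assert bce_loss(good, [1, 0]).item() < 1e-5


def test_bce_length_mismatch():
    with pytest.raises(ValueError):
        bce_loss(Tensor(np.array([0.5], dtype=np.float32)), [1, 0])


def test_fit_is_seed_deterministic(tiny_world):
    world, pairs = tiny_world
    cfg = small_model_config(seed=0)
    tc = TrainConfig(seed=11, max_epochs=2, batch_size=32, learning_rate=0.3)
    results = []
    for _ in range(2):
        model = PresentationModel(cfg)
        log = []
        best, _ = training.fit(model, pairs[:150], pairs[150:200],
                               world.registry, tc, log=log)
        preds = model.predict_pairs(pairs[200:220], world.registry)
        results.append((best, tuple(r.train_loss for r in log), preds))
    assert results[0][0] == results[1][0]
    assert results[0][1] == results[1][1]
    assert np.array_equal(results[0][2], results[1][2])


def test_early_stopping_bound(tiny_world):
    """Training halts no more than patience+1 epochs after the best epoch."""
    world, pairs = tiny_world
    cfg = small_model_config(seed=1)
    tc = TrainConfig(seed=5, max_epochs=12, batch_size=32, learning_rate=0.01,
                     early_stop_patience=2)
    model = PresentationModel(cfg)
    log = []
    _, best_epoch = training.fit(model, pairs[:120], pairs[120:170],
                                 world.registry, tc, log=log)
    last_epoch = log[-1].epoch
    assert last_epoch - best_epoch <= tc.early_stop_patience + 1


def test_train_cross_validation_protocol(tiny_world):
    world, pairs = tiny_world
    cfg = small_model_config(seed=2)
    tc = TrainConfig(seed=3, max_epochs=2, batch_size=32, learning_rate=0.3)
    model, report = training.train(pairs, world.registry, tc, cfg)
    assert len(report.fold_aurocs) == 5
    assert all(0 <= a <= 1 for a in report.fold_aurocs)
    # fold assignment never splits a peptide string across folds
    folds = training.assign_folds(pairs, 5, seed=3)
    seen = {}
    for p, f in zip(pairs, folds):
        assert seen.setdefault(p.peptide.sequence, f) == f
    # the refit model scores the whole table
    scores = model.predict_pairs(pairs[:20], world.registry)
    assert scores.shape == (20,)


def test_train_requires_enough_positives(tiny_world):
    world, pairs = tiny_world
    few = [p for p in pairs if p.label == 1][:3] + [p for p in pairs if p.label == 0][:3]
    with pytest.raises(ValueError, match="positives"):
        training.train(few, world.registry, TrainConfig(seed=0, max_epochs=1))


def test_train_rejects_unknown_allele(tiny_world):
    world, pairs = tiny_world
    with pytest.raises(KeyError):
        training.train(pairs, {}, TrainConfig(seed=0, max_epochs=1))


def test_loss_decreases_on_synthetic_world(tiny_world):
    """Gradient flow sanity: mean train loss drops over the first epochs."""
    world, pairs = tiny_world
    cfg = small_model_config(seed=4)
    tc = TrainConfig(seed=7, max_epochs=3, batch_size=32, learning_rate=0.3)
    model = PresentationModel(cfg)
    log = []
    training.fit(model, pairs[:180], pairs[180:216], world.registry, tc, log=log)
    assert log[-1].train_loss < log[0].train_loss
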