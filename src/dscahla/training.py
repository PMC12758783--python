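"""Training protocol: Adadelta, early stopping on validation AUROC, 5-fold CV.

Folds are assigned at the peptide-string level (no string crosses folds),
stratified by label within allele, mirroring the leakage-aware benchmark
deduplication.  ``fit`` trains a single model with early stopping;
``train`` runs the full cross-validation protocol and refits on all data
with the epoch budget selected by the folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import ModelConfig, TrainConfig
from .io import HLAAllele, PairExample
from .metrics import auroc_score
from .model import Featurizer, PresentationModel, bce_loss
from .nn import Adadelta, clip_grad_norm


@dataclass
class EpochRecord:
    fold: int
    epoch: int
    train_loss: float
    val_auroc: float | None


@dataclass
class FoldReport:
    records: list[EpochRecord] = field(default_factory=list)
    fold_aurocs: list[float] = field(default_factory=list)
    best_epochs: list[int] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [vars(r) for r in self.records]


def _snapshot(model: PresentationModel) -> dict[str, np.ndarray]:
    return {name: p.data.copy() for name, p in model.named_parameters()}


def _restore(model: PresentationModel, state: dict[str, np.ndarray]) -> None:
    for name, p in model.named_parameters():
        p.data = state[name].copy()


def fit(model: PresentationModel,
        train_pairs: Sequence[PairExample],
        val_pairs: Sequence[PairExample],
        registry: Mapping[str, HLAAllele],
        cfg: TrainConfig,
        featurizer: Featurizer | None = None,
        fold: int = 0,
        log: list[EpochRecord] | None = None) -> tuple[float, int]:
    """Train ``model`` in place with early stopping on validation AUROC.

    Returns (best validation AUROC, best epoch).  The model is left at the
    best-epoch parameters.  Training halts at most ``patience + 1`` epochs
    after the best validation epoch.
    """
    featurizer = featurizer or Featurizer(model.cfg)
    data = featurizer.prepare(list(train_pairs), registry)
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1000 * (fold + 1)))
    model.reseed(cfg.seed + 7919 * (fold + 1))
    params = model.parameters()
    opt = Adadelta(params, lr=cfg.learning_rate, rho=cfg.rho,
                   eps=cfg.eps, weight_decay=cfg.weight_decay)
    # start the head at the training base rate so early epochs refine ranking
    # rather than calibration
    pos_rate = float(np.clip(data.labels.mean(), 1e-3, 1 - 1e-3))
    model.head.final.bias.data[:] = np.log(pos_rate / (1.0 - pos_rate))

    best_auroc = -np.inf
    best_epoch = -1
    best_state = _snapshot(model)
    step = 0
    for epoch in range(cfg.max_epochs):
        model.set_training(True)
        order = rng.permutation(data.n)
        losses = []
        decay_steps = max(0, (epoch - cfg.lr_decay_start) // cfg.lr_decay_every)
        base_lr = cfg.learning_rate * cfg.lr_decay ** decay_steps
        for lo in range(0, data.n, cfg.batch_size):
            batch = data.take(order[lo:lo + cfg.batch_size])
            probs = model.forward(batch)
            loss = bce_loss(probs, batch.labels)
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            step += 1
            opt.lr = base_lr * min(1.0, step / max(1, cfg.warmup_steps))
            opt.step()
            losses.append(loss.item())
        val_scores = model.predict_pairs(val_pairs, registry, featurizer=featurizer)
        val_auroc = auroc_score([p.label for p in val_pairs], val_scores)
        if log is not None:
            log.append(EpochRecord(fold=fold, epoch=epoch,
                                   train_loss=float(np.mean(losses)),
                                   val_auroc=val_auroc))
        if val_auroc is not None and val_auroc > best_auroc:
            best_auroc = val_auroc
            best_epoch = epoch
            best_state = _snapshot(model)
        elif epoch - best_epoch > cfg.early_stop_patience:
            break
    _restore(model, best_state)
    return float(best_auroc), best_epoch


def assign_folds(pairs: Sequence[PairExample], n_folds: int,
                 seed: int) -> np.ndarray:
    """Peptide-level fold ids, stratified by label within allele."""
    rng = np.random.Generator(np.random.PCG64(seed))
    assignment: dict[str, int] = {}
    groups: dict[tuple[str, int], list[str]] = {}
    for p in pairs:
        groups.setdefault((p.allele, p.label), []).append(p.peptide.sequence)
    for key in sorted(groups):
        strings = [s for s in dict.fromkeys(groups[key]) if s not in assignment]
        order = rng.permutation(len(strings))
        for rank, j in enumerate(order):
            assignment[strings[j]] = rank % n_folds
    return np.array([assignment[p.peptide.sequence] for p in pairs])


def train(pairs: Sequence[PairExample], registry: Mapping[str, HLAAllele],
          cfg: TrainConfig, model_cfg: ModelConfig | None = None,
          ) -> tuple[PresentationModel, FoldReport]:
    """5-fold cross-validation, then a refit on all data.

    Per fold, a fresh model is trained with early stopping; the refit uses
    the median of the folds' best epoch counts as its fixed budget.
    """
    pairs = list(pairs)
    n_pos = sum(p.label for p in pairs)
    if n_pos < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} positives, got {n_pos}")
    unknown = sorted({p.allele for p in pairs} - set(registry))
    if unknown:
        raise KeyError(f"allele(s) not in registry: {unknown}")
    model_cfg = model_cfg or ModelConfig(seed=cfg.seed)
    featurizer = Featurizer(model_cfg)
    folds = assign_folds(pairs, cfg.n_folds, cfg.seed)
    report = FoldReport()
    for k in range(cfg.n_folds):
        tr = [p for p, f in zip(pairs, folds) if f != k]
        va = [p for p, f in zip(pairs, folds) if f == k]
        model = PresentationModel(model_cfg)
        auroc, best_epoch = fit(model, tr, va, registry, cfg,
                                featurizer=featurizer, fold=k, log=report.records)
        report.fold_aurocs.append(auroc)
        report.best_epochs.append(best_epoch)

    budget = int(np.median(report.best_epochs)) + 1
    final = PresentationModel(model_cfg)
    # refit on everything: reuse fit() with a token validation split so the
    # loop machinery is identical, but disable early stopping by patience
    data_rng = np.random.Generator(np.random.PCG64(cfg.seed))
    idx = data_rng.permutation(len(pairs))
    token_val = [pairs[i] for i in idx[:max(2, len(pairs) // 50)]]
    final_cfg = _with_epochs(cfg, budget)
    final_cfg.early_stop_patience = budget + 1
    fit(final, pairs, token_val, registry, final_cfg,
        featurizer=featurizer, fold=cfg.n_folds)
    return final, report


def _with_epochs(cfg: TrainConfig, epochs: int) -> TrainConfig:
    out = TrainConfig(**vars(cfg))
    out.max_epochs = epochs
    return out
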