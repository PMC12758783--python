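"""The presentation model: embedding -> backbone -> DSCA -> prediction head.

The batched forward computes HLA-side features once per *unique allele* in
the batch and gathers them per example afterwards; because every HLA-side
operation up to the cross-attention value product is per-sequence, this is
exactly equivalent to the naive per-example computation and is the main
reason training is tractable on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .backbone import StreamEncoder, StreamFeatures
from .config import ModelConfig
from .dsca import DscaOutput, DualStreamCrossAttention
from .embedding import (
    ResidueEmbedder,
    embed_hla,
    embed_peptide,
    hla_mask,
    hla_one_hot,
    make_provider,
    one_hot_encode,
    sequence_mask,
)
from .io import ALPHABET, HLAAllele, PairExample
from .nn import Tensor
from .nn import autograd as ag

EPS_BCE = 1e-7


def bce_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy with probability clipping at 1e-7."""
    if probs.shape[0] != len(labels):
        raise ValueError(f"{probs.shape[0]} probabilities vs {len(labels)} labels")
    y = np.asarray(labels, dtype=np.float32)
    clipped = ag.Tensor(np.clip(probs.data, EPS_BCE, 1.0 - EPS_BCE))
    clipped._parents = (probs,)
    clipped._backward = lambda g: (g * ((probs.data > EPS_BCE) & (probs.data < 1 - EPS_BCE)),)
    term = ag.mul(ag.log(clipped), Tensor(y)) + ag.mul(
        ag.log(Tensor(np.float32(1.0)) - clipped), Tensor(1.0 - y))
    return -reduce_to_mean(term)


def reduce_to_mean(t: Tensor) -> Tensor:
    return ag.reduce_mean(t, axis=None)


@dataclass
class PreparedBatch:
    """Featurized arrays for a batch of peptide-allele pairs."""

    pep_onehot: np.ndarray            # (B, L_pep, 21)
    pep_plm: np.ndarray | None        # (B, L_pep, d_plm)
    pep_mask: np.ndarray              # (B, L_pep) bool
    hla_onehot: np.ndarray            # (A, L_hla, 21)
    hla_plm: np.ndarray | None        # (A, L_hla, d_plm)
    hla_mask: np.ndarray              # (A, L_hla) bool
    allele_index: np.ndarray          # (B,) int -> rows of the allele arrays
    labels: np.ndarray | None = None  # (B,) {0,1}

    def take(self, idx: np.ndarray) -> "PreparedBatch":
        return PreparedBatch(
            pep_onehot=self.pep_onehot[idx],
            pep_plm=None if self.pep_plm is None else self.pep_plm[idx],
            pep_mask=self.pep_mask[idx],
            hla_onehot=self.hla_onehot,
            hla_plm=self.hla_plm,
            hla_mask=self.hla_mask,
            allele_index=self.allele_index[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    @property
    def n(self) -> int:
        return self.pep_onehot.shape[0]


class Featurizer:
    """Turns pair lists into model-ready arrays, with per-sequence caching."""

    def __init__(self, cfg: ModelConfig, provider=None):
        self.cfg = cfg
        self.provider = provider or make_provider(cfg.embedding.provider,
                                                  cfg.embedding.d_plm)
        self._pep_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._hla_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _peptide(self, seq: str):
        hit = self._pep_cache.get(seq)
        if hit is None:
            l_pep = self.cfg.embedding.l_pep
            onehot = one_hot_encode(seq, l_pep)
            plm = embed_peptide(seq, self.provider, l_pep).values \
                if self.cfg.embedding.use_plm else None
            hit = (onehot, plm, sequence_mask(seq, l_pep))
            self._pep_cache[seq] = hit
        return hit

    def _allele(self, allele: HLAAllele):
        hit = self._hla_cache.get(allele.name)
        if hit is None:
            l_chain = self.cfg.embedding.l_chain
            onehot = hla_one_hot(allele, l_chain)
            plm = embed_hla(allele, self.provider, l_chain).values \
                if self.cfg.embedding.use_plm else None
            hit = (onehot, plm, hla_mask(allele, l_chain))
            self._hla_cache[allele.name] = hit
        return hit

    def prepare(self, pairs: Sequence[PairExample],
                registry: Mapping[str, HLAAllele]) -> PreparedBatch:
        unknown = sorted({p.allele for p in pairs} - set(registry))
        if unknown:
            raise KeyError(f"allele(s) not in registry: {unknown}")
        allele_names = sorted({p.allele for p in pairs})
        name_to_idx = {n: i for i, n in enumerate(allele_names)}
        pep_feats = [self._peptide(p.peptide.sequence) for p in pairs]
        hla_feats = [self._allele(registry[n]) for n in allele_names]
        use_plm = self.cfg.embedding.use_plm
        return PreparedBatch(
            pep_onehot=np.stack([f[0] for f in pep_feats]),
            pep_plm=np.stack([f[1] for f in pep_feats]) if use_plm else None,
            pep_mask=np.stack([f[2] for f in pep_feats]),
            hla_onehot=np.stack([f[0] for f in hla_feats]),
            hla_plm=np.stack([f[1] for f in hla_feats]) if use_plm else None,
            hla_mask=np.stack([f[2] for f in hla_feats]),
            allele_index=np.array([name_to_idx[p.allele] for p in pairs]),
            labels=np.array([p.label for p in pairs], dtype=np.float32),
        )


class PredictionHead(nn.Module):
    """Global max pooling of both streams, MLP, linear projection, sigmoid."""

    def __init__(self, d_model: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.mlp1 = nn.Linear(2 * d_model, d_model, rng)
        self.mlp2 = nn.Linear(d_model, max(d_model // 2, 1), rng)
        self.final = nn.Linear(max(d_model // 2, 1), 1, rng)
        self.p_drop = dropout

    def pool_and_concat(self, h_pep: Tensor, h_hla: Tensor,
                        pep_mask: np.ndarray, hla_mask: np.ndarray) -> Tensor:
        g_pep = ag.masked_max(h_pep, pep_mask, axis=1)
        g_hla = ag.masked_max(h_hla, hla_mask, axis=1)
        return ag.concat([g_pep, g_hla], axis=-1)

    def predict_probability(self, interaction: Tensor,
                            rng: np.random.Generator) -> Tensor:
        if not np.isfinite(interaction.data).all():
            raise ValueError("non-finite interaction features")
        x = ag.gelu(self.mlp1(interaction))
        x = ag.dropout(x, self.p_drop, rng, self.training)
        x = ag.gelu(self.mlp2(x))
        x = ag.dropout(x, self.p_drop, rng, self.training)
        logits = self.final(x)
        return ag.sigmoid(ag.reduce_sum(logits, axis=-1))


class PresentationModel(nn.Module):
    """End-to-end peptide-HLA-II presentation predictor."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.Generator(np.random.PCG64(cfg.seed))
        emb = cfg.embedding
        self.embedder_pep = ResidueEmbedder(emb.d_plm, emb.d_plm_proj, rng,
                                            emb.use_plm, emb.use_context)
        self.embedder_hla = ResidueEmbedder(emb.d_plm, emb.d_plm_proj, rng,
                                            emb.use_plm, emb.use_context)
        d_fused = self.embedder_pep.d_fused
        self.enc_pep = StreamEncoder(d_fused, cfg.backbone, "peptide", emb.l_pep, rng)
        self.enc_hla = StreamEncoder(d_fused, cfg.backbone, "hla", 2 * emb.l_chain, rng)
        self.dsca = DualStreamCrossAttention(cfg.backbone, cfg.dsca, rng)
        self.head = PredictionHead(cfg.backbone.d_model, cfg.head.dropout, rng)
        self._rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))

    def reseed(self, seed: int):
        """Reset the dropout stream (training reproducibility)."""
        self._rng = np.random.Generator(np.random.PCG64(seed))

    # -- forward --------------------------------------------------------
    def _stream_features(self, batch: PreparedBatch):
        rng = self._rng
        fused_p = self.embedder_pep.fuse(
            None if batch.pep_plm is None else Tensor(batch.pep_plm),
            Tensor(batch.pep_onehot), batch.pep_mask)
        pep = self.enc_pep(fused_p, batch.pep_mask, rng)
        fused_h = self.embedder_hla.fuse(
            None if batch.hla_plm is None else Tensor(batch.hla_plm),
            Tensor(batch.hla_onehot), batch.hla_mask)
        hla = self.enc_hla(fused_h, batch.hla_mask, rng)  # per unique allele
        return pep, hla

    def forward(self, batch: PreparedBatch, return_attn: bool = False):
        """Presentation probabilities for a prepared batch.

        Returns ``probs`` (B,) or, with ``return_attn``, ``(probs, DscaOutput)``.
        """
        pep, hla = self._stream_features(batch)
        idx = batch.allele_index
        d_model = self.cfg.backbone.d_model

        if self.dsca.mode == "conventional":
            hla_local_b = ag.gather_rows(hla.local_features, idx)
            from .dsca import dsca_stream
            o, attn_pep = dsca_stream(
                pep.global_features, hla_local_b, hla_local_b,
                self.dsca.pep_stream.w_q, self.dsca.pep_stream.w_k,
                self.dsca.pep_stream.w_v)
            h_pep = self.dsca.pep_stream.finalize(o, pep.global_features)
            h_hla = ag.gather_rows(hla.global_features, idx)
            attn_hla = Tensor(np.zeros((batch.n, h_hla.shape[1], attn_pep.shape[-1]),
                                       dtype=np.float32))
        else:
            # peptide stream: self = peptide, values gathered from the HLA side
            ps = self.dsca.pep_stream
            q_p = ps.w_q(pep.global_features)
            k_p = ps.w_k(pep.local_features)
            attn_pep = ag.masked_softmax(
                ag.matmul(q_p, ag.swap_last(k_p)) / np.sqrt(d_model))
            v_h = ag.gather_rows(ps.w_v(hla.local_features), idx)
            o_p = ag.l2_normalize(ag.matmul(attn_pep, v_h))
            h_pep = ps.finalize(o_p, pep.global_features)

            # HLA stream: Q, K and the attention map are per allele; values per example
            hs = self.dsca.hla_stream
            q_h = hs.w_q(hla.global_features)
            k_h = hs.w_k(hla.local_features)
            attn_hla_allele = ag.masked_softmax(
                ag.matmul(q_h, ag.swap_last(k_h)) / np.sqrt(d_model))
            attn_hla = ag.gather_rows(attn_hla_allele, idx)
            v_p = hs.w_v(pep.local_features)
            o_h = ag.l2_normalize(ag.matmul(attn_hla, v_p))
            h_hla = hs.finalize(o_h, ag.gather_rows(hla.global_features, idx))

        interaction = self.head.pool_and_concat(
            h_pep, h_hla, batch.pep_mask, batch.hla_mask[idx])
        probs = self.head.predict_probability(interaction, self._rng)
        if return_attn:
            return probs, DscaOutput(h_pep=h_pep, h_hla=h_hla,
                                     attn_pep=attn_pep, attn_hla=attn_hla)
        return probs

    # -- inference API --------------------------------------------------
    def predict_pairs(self, pairs: Sequence[PairExample],
                      registry: Mapping[str, HLAAllele],
                      featurizer: Featurizer | None = None,
                      batch_size: int = 256,
                      return_attn: bool = False):
        """Score pairs in evaluation mode; optionally keep peptide attention maps."""
        featurizer = featurizer or Featurizer(self.cfg)
        self.set_training(False)
        probs_out: list[np.ndarray] = []
        attn_out: list[np.ndarray] = []
        for lo in range(0, len(pairs), batch_size):
            chunk = list(pairs[lo:lo + batch_size])
            batch = featurizer.prepare(chunk, registry)
            if return_attn:
                probs, out = self.forward(batch, return_attn=True)
                attn_out.append(out.attn_pep.data)
            else:
                probs = self.forward(batch)
            probs_out.append(probs.data)
        probs = np.concatenate(probs_out) if probs_out else np.zeros(0)
        if return_attn:
            attn = np.concatenate(attn_out) if attn_out else np.zeros((0, 0, 0))
            return probs, attn
        return probs

    # -- persistence ----------------------------------------------------
    def save(self, path):
        meta = {"config": self.cfg.to_dict(), "alphabet": ALPHABET,
                "format_version": 1}
        arrays = {name: p.data for name, p in self.named_parameters()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "PresentationModel":
        with np.load(path) as blob:
            meta = json.loads(bytes(blob["__meta__"].tobytes()).decode())
            model = cls(ModelConfig.from_dict(meta["config"]))
            named = dict(model.named_parameters())
            for name in blob.files:
                if name == "__meta__":
                    continue
                if name not in named:
                    raise ValueError(f"checkpoint parameter {name!r} not in model")
                if named[name].data.shape != blob[name].shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                named[name].data = blob[name].copy()
        return model
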