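"""Dual-stream cross-attention (DSCA).

Each stream queries with its *own* global features, keys with its *own*
local features, and takes values from the *other* stream's local features:

    Q = X_self_global W_Q,  K = H_self_local W_K,  V = H_other_local W_V
    Attn = row-softmax(Q K^T / sqrt(d_global))
    O[i, d] = sum_j Attn[i, j] V[j, d]
    O~ = row-wise L2 normalization of O
    H = Conv1D_same(O~) + X_self_global

The Query-Key product localizes informative windows of the stream's own
sequence; the Value path imports the aligned windows of the partner
sequence, so gradients flow across streams.  The finishing convolution uses
the stream's encoding kernel size (9 peptide / 5 HLA) in length-preserving
mode with fresh weights, so the residual addition is shape-legal.  The two
streams carry independent parameter sets.

A conventional single-stream cross-attention ablation (Q from the peptide,
K and V both from the HLA) is selectable via ``DscaConfig.mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import StreamFeatures
from .config import BackboneConfig, DscaConfig
from .nn import Tensor
from .nn import autograd as ag


@dataclass
class DscaOutput:
    """Fused stream features plus the attention maps used for core scoring."""

    h_pep: Tensor
    h_hla: Tensor
    attn_pep: Tensor  # (B, L_pep_std, L_loc)
    attn_hla: Tensor  # (B, L_hla_std, L_loc)


def dsca_stream(self_global: Tensor, self_local: Tensor, other_local: Tensor,
                w_q: nn.Linear, w_k: nn.Linear, w_v: nn.Linear) -> tuple[Tensor, Tensor]:
    """One stream of cross-attention; returns (row-normalized output, attention map)."""
    if self_local.shape[-2] != other_local.shape[-2]:
        raise ValueError(
            f"local length mismatch: {self_local.shape[-2]} vs {other_local.shape[-2]}")
    q = w_q(self_global)
    k = w_k(self_local)
    v = w_v(other_local)
    d_global = self_global.shape[-1]
    attn = ag.masked_softmax(ag.matmul(q, ag.swap_last(k)) / np.sqrt(d_global))
    o = ag.matmul(attn, v)
    return ag.l2_normalize(o), attn


class DscaStreamParams(nn.Module):
    """Projection and finishing-convolution parameters of one stream."""

    def __init__(self, d_model: int, d_attn: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.w_q = nn.Linear(d_model, d_attn, rng, bias=False)
        self.w_k = nn.Linear(d_model, d_attn, rng, bias=False)
        self.w_v = nn.Linear(d_model, d_attn, rng, bias=False)
        self.final_conv = nn.Conv1d(d_attn, d_model, kernel, rng, mode="same")
        # O~ rows are unit-L2 (entries ~ 1/sqrt(d)); rescale the finishing
        # convolution so its output is commensurate with the layer-normalized
        # global features it is added to
        self.final_conv.weight.data *= np.sqrt(d_attn)

    def attend(self, self_global: Tensor, self_local: Tensor,
               other_local: Tensor) -> tuple[Tensor, Tensor]:
        return dsca_stream(self_global, self_local, other_local,
                           self.w_q, self.w_k, self.w_v)

    def finalize(self, o_norm: Tensor, self_global: Tensor) -> Tensor:
        out = self.final_conv(o_norm) + self_global
        if out.shape != self_global.shape:
            raise RuntimeError("finishing convolution changed the sequence shape")
        return out


class DualStreamCrossAttention(nn.Module):
    def __init__(self, backbone_cfg: BackboneConfig, dsca_cfg: DscaConfig,
                 rng: np.random.Generator):
        super().__init__()
        d_attn = dsca_cfg.d_attn or backbone_cfg.d_model
        self.mode = dsca_cfg.mode
        if self.mode not in ("dual", "conventional"):
            raise ValueError(f"unknown DSCA mode {self.mode!r}")
        self.pep_stream = DscaStreamParams(backbone_cfg.d_model, d_attn,
                                           backbone_cfg.kernel_pep, rng)
        self.hla_stream = DscaStreamParams(backbone_cfg.d_model, d_attn,
                                           backbone_cfg.kernel_hla, rng)

    def __call__(self, pep: StreamFeatures, hla: StreamFeatures) -> DscaOutput:
        if self.mode == "conventional":
            return self._conventional(pep, hla)
        o_pep, attn_pep = self.pep_stream.attend(
            pep.global_features, pep.local_features, hla.local_features)
        o_hla, attn_hla = self.hla_stream.attend(
            hla.global_features, hla.local_features, pep.local_features)
        return DscaOutput(
            h_pep=self.pep_stream.finalize(o_pep, pep.global_features),
            h_hla=self.hla_stream.finalize(o_hla, hla.global_features),
            attn_pep=attn_pep,
            attn_hla=attn_hla,
        )

    def _conventional(self, pep: StreamFeatures, hla: StreamFeatures) -> DscaOutput:
        """Single-stream baseline: Q from the peptide, K and V both from the HLA."""
        o, attn = dsca_stream(pep.global_features, hla.local_features, hla.local_features,
                              self.pep_stream.w_q, self.pep_stream.w_k, self.pep_stream.w_v)
        h_pep = self.pep_stream.finalize(o, pep.global_features)
        b = attn.shape[0]
        flat_hla = np.zeros((b, hla.global_features.shape[-2], attn.shape[-1]),
                            dtype=np.float32)
        return DscaOutput(h_pep=h_pep, h_hla=hla.global_features,
                          attn_pep=attn, attn_hla=Tensor(flat_hla))
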