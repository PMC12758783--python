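"""Global (transformer) and local (convolutional) feature extraction.

Each stream turns a fused residue representation into
  * global features: input projection + fixed sinusoidal positions, then a
    stack of post-norm transformer encoder layers with pad masking, and
  * local features: a valid-window 1-D convolution (kernel 9 for peptides so
    each window is one candidate binding core; kernel 5 for HLA pockets),
    adaptively max-pooled to a shared local length so cross-stream attention
    between the two streams is well-formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import BackboneConfig
from .nn import Tensor
from .nn import autograd as ag


@dataclass
class StreamFeatures:
    """Per-sequence global (L_std x d_model) and local (L_loc x d_model) features."""

    global_features: Tensor
    local_features: Tensor
    mask: np.ndarray


class StreamEncoder(nn.Module):
    """Backbone for one stream (peptide or HLA)."""

    def __init__(self, d_fused: int, cfg: BackboneConfig, kind: str,
                 seq_len: int, rng: np.random.Generator):
        super().__init__()
        if kind not in ("peptide", "hla"):
            raise ValueError(f"kind must be 'peptide' or 'hla', got {kind!r}")
        self.kind = kind
        self.cfg = cfg
        self.seq_len = seq_len
        self.kernel = cfg.kernel_pep if kind == "peptide" else cfg.kernel_hla
        if seq_len < self.kernel:
            raise ValueError(f"sequence length {seq_len} shorter than kernel {self.kernel}")
        self.input_proj = nn.Linear(d_fused, cfg.d_model, rng)
        self.positions = nn.sinusoidal_positions(seq_len, cfg.d_model)
        self.layers = [
            nn.TransformerEncoderLayer(cfg.d_model, cfg.n_heads,
                                       cfg.ffn_mult * cfg.d_model, cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]
        self.local_conv = nn.Conv1d(d_fused, cfg.d_model, self.kernel, rng, mode="valid")

    @property
    def n_windows(self) -> int:
        """Valid convolution windows before pooling (candidate core starts for peptides)."""
        return self.seq_len - self.kernel + 1

    def encode_global(self, fused: Tensor, mask: np.ndarray,
                      rng: np.random.Generator) -> Tensor:
        x = self.input_proj(fused) + Tensor(self.positions)
        for layer in self.layers:
            x = layer(x, mask, rng)
        return x

    def encode_local(self, fused: Tensor) -> Tensor:
        """Rectified convolution block over the sequence axis.

        The rectification matters: downstream cross-attention aggregates
        windows by (near-uniform, early in training) weighted averaging, and
        only rectified window activations keep "a binding-core-like window
        exists somewhere" visible through an average.
        """
        h = ag.relu(self.local_conv(fused))
        if h.shape[1] != self.cfg.l_loc:
            h = ag.adaptive_max_pool(h, self.cfg.l_loc)
        return h

    def __call__(self, fused: Tensor, mask: np.ndarray,
                 rng: np.random.Generator) -> StreamFeatures:
        return StreamFeatures(
            global_features=self.encode_global(fused, mask, rng),
            local_features=self.encode_local(fused),
            mask=mask,
        )
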