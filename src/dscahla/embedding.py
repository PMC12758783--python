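"""Per-residue representations: one-hot, context enhancement and PLM adapters.

The fused residue representation of a sequence concatenates three blocks
along the feature axis: a (projected) protein-language-model embedding, the
raw one-hot encoding, and a context-enhanced one-hot produced by a
single-head self-attention layer.  Sequences are standardized to fixed
lengths (32 for peptides, 100 per HLA chain giving 200 for the
alpha+beta concatenation) by C-terminal zero-padding or truncation, so the
N-terminal register that anchor analysis depends on is preserved.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import nn
from .io import AA_INDEX, ALPHABET, HLAAllele
from .nn import Tensor
from .nn import autograd as ag

L_PEP_STD = 32
L_CHAIN_STD = 100


class EmbeddingProviderError(RuntimeError):
    """A protein-language-model provider failed to produce an embedding."""


@dataclass
class PlmEmbedding:
    """Standardized per-residue PLM embedding (rows = positions)."""

    values: np.ndarray
    provider_tag: str
    d_plm: int


def one_hot_encode(sequence: str, target_len: int) -> np.ndarray:
    """Encode a sequence as a (target_len x 21) indicator matrix.

    Rows beyond the sequence are all-zero padding; sequences longer than
    ``target_len`` are truncated from the C-terminal end.
    """
    if not sequence:
        raise ValueError("cannot one-hot encode an empty sequence")
    mat = np.zeros((target_len, len(ALPHABET)), dtype=np.float32)
    for i, aa in enumerate(sequence[:target_len]):
        try:
            mat[i, AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"illegal residue {aa!r} at position {i}") from None
    return mat


def sequence_mask(sequence: str, target_len: int) -> np.ndarray:
    mask = np.zeros(target_len, dtype=bool)
    mask[:min(len(sequence), target_len)] = True
    return mask


def standardize(values: np.ndarray, target_len: int) -> np.ndarray:
    """Pad (zero rows, C-terminal) or truncate a per-residue matrix to target_len rows."""
    l, d = values.shape
    if l >= target_len:
        return values[:target_len]
    out = np.zeros((target_len, d), dtype=values.dtype)
    out[:l] = values
    return out


class FallbackHashProvider:
    """Deterministic, download-free per-residue embedding.

    Each position is represented by a fixed pseudo-random vector keyed by the
    residue's 3-mer context (previous, self, next; '-' at the termini).  The
    table is derived from a stable hash, so the embedding is bit-reproducible
    across processes with no model weights involved.  It carries exactly the
    local-composition information a short convolution could recover, which is
    enough to exercise and test the full pipeline offline.
    """

    tag = "fallback-hash"

    def __init__(self, d_plm: int = 32):
        self.d_plm = d_plm
        self._table: dict[str, np.ndarray] = {}

    def _vector(self, context: str) -> np.ndarray:
        vec = self._table.get(context)
        if vec is None:
            digest = hashlib.blake2b(f"{context}|{self.d_plm}".encode(), digest_size=8).digest()
            seed = int.from_bytes(digest, "little") % (2 ** 63)
            rng = np.random.Generator(np.random.PCG64(seed))
            vec = rng.standard_normal(self.d_plm).astype(np.float32)
            vec /= np.sqrt(self.d_plm)
            self._table[context] = vec
        return vec

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise EmbeddingProviderError("fallback provider: empty sequence")
        padded = f"-{sequence}-"
        return np.stack([self._vector(padded[i:i + 3]) for i in range(len(sequence))])


class EsmcAdapter:
    """Adapter for the external ESMC-600M protein language model.

    Requires the optional ``esm`` client package; absent that, construction
    raises :class:`EmbeddingProviderError` so callers fall back explicitly.
    """

    tag = "esmc-600m"
    d_plm = 1152

    def __init__(self, model_name: str = "esmc_600m"):
        try:
            from esm.models.esmc import ESMC  # type: ignore
            from esm.sdk.api import ESMProtein, LogitsConfig  # type: ignore
        except ImportError as exc:
            raise EmbeddingProviderError(
                "the 'esm' client package is not installed; use the fallback provider"
            ) from exc
        self._ESMProtein = ESMProtein
        self._LogitsConfig = LogitsConfig
        self._client = ESMC.from_pretrained(model_name)

    def embed(self, sequence: str) -> np.ndarray:
        try:
            protein = self._ESMProtein(sequence=sequence)
            tensor = self._client.encode(protein)
            out = self._client.logits(
                tensor, self._LogitsConfig(sequence=True, return_embeddings=True))
            emb = np.asarray(out.embeddings[0], dtype=np.float32)
        except Exception as exc:  # pragma: no cover - external service path
            raise EmbeddingProviderError(f"ESMC embedding failed: {exc}") from exc
        # strip BOS/EOS tokens if the client added them
        if emb.shape[0] == len(sequence) + 2:
            emb = emb[1:-1]
        return emb


def make_provider(name: str, d_plm: int = 32):
    if name == "fallback-hash":
        return FallbackHashProvider(d_plm=d_plm)
    if name == "esmc-600m":
        return EsmcAdapter()
    raise ValueError(f"unknown embedding provider {name!r}")


def embed_peptide(sequence: str, provider, target_len: int = L_PEP_STD) -> PlmEmbedding:
    """Per-residue PLM embedding of a peptide, standardized to ``target_len`` rows."""
    values = standardize(provider.embed(sequence), target_len)
    return PlmEmbedding(values=values, provider_tag=provider.tag, d_plm=provider.d_plm)


def embed_hla(allele: HLAAllele, provider, chain_len: int = L_CHAIN_STD) -> PlmEmbedding:
    """Embed the alpha and beta chains independently and stack them.

    Each chain is standardized to ``chain_len`` rows; the result concatenates
    alpha rows then beta rows (2 * chain_len total).
    """
    alpha = standardize(provider.embed(allele.alpha_chain), chain_len)
    beta = standardize(provider.embed(allele.beta_chain), chain_len)
    return PlmEmbedding(values=np.concatenate([alpha, beta], axis=0),
                        provider_tag=provider.tag, d_plm=provider.d_plm)


def hla_one_hot(allele: HLAAllele, chain_len: int = L_CHAIN_STD) -> np.ndarray:
    return np.concatenate([one_hot_encode(allele.alpha_chain, chain_len),
                           one_hot_encode(allele.beta_chain, chain_len)], axis=0)


def hla_mask(allele: HLAAllele, chain_len: int = L_CHAIN_STD) -> np.ndarray:
    return np.concatenate([sequence_mask(allele.alpha_chain, chain_len),
                           sequence_mask(allele.beta_chain, chain_len)])


class ResidueEmbedder(nn.Module):
    """Trainable fusion of PLM, one-hot and context-enhanced one-hot blocks.

    The PLM block is linearly projected to ``d_plm_proj`` before
    concatenation; the context block is a single-head self-attention over the
    one-hot encoding (key width 21).  Pad rows of the output are zeroed.
    """

    def __init__(self, d_plm: int, d_plm_proj: int, rng: np.random.Generator,
                 use_plm: bool = True, use_context: bool = True):
        super().__init__()
        self.use_plm = use_plm
        self.use_context = use_context
        self.n_symbols = len(ALPHABET)
        self.plm_proj = nn.Linear(d_plm, d_plm_proj, rng) if use_plm else None
        self.context_attn = nn.SelfAttention(self.n_symbols, self.n_symbols, rng) \
            if use_context else None

    @property
    def d_fused(self) -> int:
        d = self.n_symbols
        if self.plm_proj is not None:
            d += self.plm_proj.weight.shape[1]
        if self.context_attn is not None:
            d += self.n_symbols
        return d

    def context_enhance(self, onehot: Tensor, mask: np.ndarray) -> Tensor:
        """Self-attention over non-pad positions of the one-hot encoding."""
        if not mask.any(axis=-1).all():
            raise ValueError("context enhancement needs at least one real residue per sequence")
        return self.context_attn(onehot, mask)

    def fuse(self, plm: Tensor | None, onehot: Tensor, mask: np.ndarray) -> Tensor:
        """Build the fused per-residue representation for a batch.

        ``plm``: (B, L, d_plm) or None when the PLM block is ablated;
        ``onehot``: (B, L, 21); ``mask``: (B, L) bool.  Output (B, L, d_fused)
        with zero pad rows.
        """
        blocks: list[Tensor] = []
        if self.plm_proj is not None:
            if plm is None:
                raise ValueError("PLM block enabled but no PLM embedding supplied")
            if plm.shape[:2] != onehot.shape[:2]:
                raise ValueError(f"row-count mismatch: plm {plm.shape} vs onehot {onehot.shape}")
            blocks.append(self.plm_proj(plm))
        blocks.append(onehot)
        if self.context_attn is not None:
            blocks.append(self.context_enhance(onehot, mask))
        fused = ag.concat(blocks, axis=-1)
        return fused * Tensor(mask[..., None].astype(np.float32))
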