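"""Backbone and dual-stream cross-attention contracts, with brute-force oracles."""

import numpy as np
import pytest

from dscahla import datasets
from dscahla.backbone import StreamEncoder, StreamFeatures
from dscahla.config import BackboneConfig, DscaConfig
from dscahla.dsca import DscaStreamParams, DualStreamCrossAttention, dsca_stream
from dscahla.model import Featurizer, PresentationModel, bce_loss
from dscahla.nn import Linear, Tensor
from dscahla.nn import autograd as ag

from conftest import small_model_config


def _encoder(kind, seq_len, d_fused=10, **kw):
    base = dict(d_model=16, n_layers=3, n_heads=2, ffn_mult=2, dropout=0.0)
    base.update(kw)
    cfg = BackboneConfig(**base)
    rng = np.random.default_rng(0)
    return StreamEncoder(d_fused, cfg, kind, seq_len, rng), cfg, rng


def test_global_output_shapes():
    rng = np.random.default_rng(1)
    enc_p, _, _ = _encoder("peptide", 32)
    x = Tensor(rng.normal(size=(2, 32, 10)).astype(np.float32))
    out = enc_p.encode_global(x, np.ones((2, 32), bool), rng)
    assert out.shape == (2, 32, 16)
    enc_h, _, _ = _encoder("hla", 200)
    xh = Tensor(rng.normal(size=(2, 200, 10)).astype(np.float32))
    assert enc_h.encode_global(xh, np.ones((2, 200), bool), rng).shape == (2, 200, 16)


def test_encoder_reduces_to_double_layernorm_with_zeroed_weights():
    """With MHSA output and FFN zeroed, each layer is LN(LN(x))."""
    enc, _, rng = _encoder("peptide", 12)
    x = np.random.default_rng(3).normal(size=(1, 12, 16)).astype(np.float32)
    layer = enc.layers[0]
    layer.mhsa.w_o.weight.data[:] = 0
    layer.ffn2.weight.data[:] = 0
    layer.ffn2.bias.data[:] = 0
    out = layer(Tensor(x), np.ones((1, 12), bool), rng)

    def ln(v, gain, bias):
        mu = v.mean(-1, keepdims=True)
        sd = np.sqrt(((v - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
        return (v - mu) / sd * gain + bias

    expected = ln(ln(x, layer.ln1.gain.data, layer.ln1.bias.data),
                  layer.ln2.gain.data, layer.ln2.bias.data)
    assert np.allclose(out.data, expected, atol=1e-5)


def test_encoder_is_permutation_sensitive():
    enc, _, rng = _encoder("peptide", 12)
    x = np.random.default_rng(4).normal(size=(1, 12, 10)).astype(np.float32)
    perm = x[:, ::-1].copy()
    mask = np.ones((1, 12), bool)
    a = enc.encode_global(Tensor(x), mask, np.random.default_rng(0))
    b = enc.encode_global(Tensor(perm), mask, np.random.default_rng(0))
    assert not np.allclose(a.data[:, 0], b.data[:, -1], atol=1e-4)


def test_local_window_counts_and_pooling():
    enc_p, cfg, _ = _encoder("peptide", 32)
    assert enc_p.n_windows == 32 - 9 + 1 == 24
    enc_h, _, _ = _encoder("hla", 200)
    assert enc_h.n_windows == 200 - 5 + 1 == 196
    x = Tensor(np.random.default_rng(5).normal(size=(2, 200, 10)).astype(np.float32))
    assert enc_h.encode_local(x).shape == (2, cfg.l_loc, 16)


def test_local_conv_translation_invariance():
    """A constant input yields constant window activations."""
    enc, cfg, _ = _encoder("peptide", 32)
    x = Tensor(np.ones((1, 32, 10), dtype=np.float32))
    h = enc.encode_local(x)
    assert np.allclose(h.data[0], h.data[0, 0], atol=1e-6)


def test_sequence_shorter_than_kernel_rejected():
    with pytest.raises(ValueError, match="kernel"):
        _encoder("peptide", 8)


def test_heads_must_divide_d_model():
    with pytest.raises(ValueError, match="divisible"):
        _encoder("peptide", 32, n_heads=5)


# -- DSCA ---------------------------------------------------------------

def _stream_params(d_model=6, d_attn=6, kernel=3, seed=0):
    return DscaStreamParams(d_model, d_attn, kernel, np.random.default_rng(seed))


def test_dsca_uniform_attention_for_constant_self_features():
    """Identity projections + constant Q/K features give uniform attention and
    rows of O equal to the column mean of V."""
    d = 4
    params = _stream_params(d_model=d, d_attn=d)
    for w in (params.w_q, params.w_k, params.w_v):
        w.weight.data = np.eye(d, dtype=np.float32)
    self_global = Tensor(np.ones((1, 3, d), dtype=np.float32))
    self_local = Tensor(np.ones((1, 2, d), dtype=np.float32))
    other_local = Tensor(np.random.default_rng(1).normal(size=(1, 2, d)).astype(np.float32))
    o_norm, attn = params.attend(self_global, self_local, other_local)
    assert np.allclose(attn.data, 0.5, atol=1e-6)
    mean_v = other_local.data[0].mean(axis=0)
    expected = mean_v / np.linalg.norm(mean_v)
    assert np.allclose(o_norm.data[0], expected, atol=1e-5)


def test_dsca_attention_rows_sum_to_one_and_unit_norm_output():
    rng = np.random.default_rng(2)
    params = _stream_params(d_model=8, d_attn=8)
    o_norm, attn = params.attend(
        Tensor(rng.normal(size=(2, 5, 8)).astype(np.float32)),
        Tensor(rng.normal(size=(2, 3, 8)).astype(np.float32)),
        Tensor(rng.normal(size=(2, 3, 8)).astype(np.float32)))
    assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)
    assert np.allclose(np.linalg.norm(o_norm.data, axis=-1), 1.0, atol=1e-6)


def test_dsca_matches_index_loop_oracle():
    """Entry-by-entry loop evaluation of the stream equations on tiny instances."""
    rng = np.random.default_rng(7)
    for trial in range(5):
        l_std, l_loc, d = 4, 3, 3
        params = _stream_params(d_model=d, d_attn=d, seed=trial)
        g = rng.normal(size=(1, l_std, d))
        sl = rng.normal(size=(1, l_loc, d))
        ol = rng.normal(size=(1, l_loc, d))
        o_norm, attn = params.attend(Tensor(g.astype(np.float32)),
                                     Tensor(sl.astype(np.float32)),
                                     Tensor(ol.astype(np.float32)))
        wq, wk, wv = (params.w_q.weight.data, params.w_k.weight.data,
                      params.w_v.weight.data)
        q = np.array([[sum(g[0, i, a] * wq[a, b] for a in range(d))
                       for b in range(d)] for i in range(l_std)])
        k = np.array([[sum(sl[0, j, a] * wk[a, b] for a in range(d))
                       for b in range(d)] for j in range(l_loc)])
        v = np.array([[sum(ol[0, j, a] * wv[a, b] for a in range(d))
                       for b in range(d)] for j in range(l_loc)])
        scores = np.array([[sum(q[i, a] * k[j, a] for a in range(d)) / np.sqrt(d)
                            for j in range(l_loc)] for i in range(l_std)])
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a_ref = e / e.sum(axis=1, keepdims=True)
        o_ref = np.array([[sum(a_ref[i, j] * v[j, c] for j in range(l_loc))
                           for c in range(d)] for i in range(l_std)])
        o_ref = o_ref / (np.linalg.norm(o_ref, axis=1, keepdims=True) + 1e-8)
        assert np.allclose(attn.data[0], a_ref, atol=1e-6)
        assert np.allclose(o_norm.data[0], o_ref, atol=1e-6)


def test_dsca_local_length_mismatch_errors():
    params = _stream_params()
    with pytest.raises(ValueError, match="mismatch"):
        params.attend(Tensor(np.zeros((1, 4, 6), np.float32)),
                      Tensor(np.zeros((1, 3, 6), np.float32)),
                      Tensor(np.zeros((1, 2, 6), np.float32)))


def test_finalize_residual_identity_under_zeroed_conv():
    params = _stream_params(d_model=6, d_attn=6, kernel=3)
    params.final_conv.weight.data[:] = 0
    params.final_conv.bias.data[:] = 0
    g = Tensor(np.random.default_rng(1).normal(size=(1, 5, 6)).astype(np.float32))
    o = Tensor(np.random.default_rng(2).normal(size=(1, 5, 6)).astype(np.float32))
    out = params.finalize(o, g)
    assert np.allclose(out.data, g.data)
    assert out.shape == g.shape


def test_finalize_perturbation_locality():
    """Perturbing one row of O~ changes only rows within the kernel radius."""
    params = _stream_params(d_model=6, d_attn=6, kernel=3)
    g = Tensor(np.zeros((1, 9, 6), dtype=np.float32))
    o1 = np.random.default_rng(3).normal(size=(1, 9, 6)).astype(np.float32)
    o2 = o1.copy()
    o2[0, 4] += 1.0
    a = params.finalize(Tensor(o1), g).data
    b = params.finalize(Tensor(o2), g).data
    changed = np.any(a != b, axis=2)[0]
    assert changed[3:6].any()
    assert not changed[:3].any() and not changed[6:].any()


def test_dual_stream_asymmetry_and_shapes(tiny_world):
    world, pairs = tiny_world
    cfg = small_model_config(seed=1)
    model = PresentationModel(cfg)
    model.set_training(False)
    feat = Featurizer(cfg)
    batch = feat.prepare(pairs[:8], world.registry)
    _, out = model.forward(batch, return_attn=True)
    l_loc = cfg.backbone.l_loc
    assert out.attn_pep.shape == (8, 32, l_loc)
    assert out.attn_hla.shape == (8, 2 * cfg.embedding.l_chain, l_loc)
    # the two streams carry independent parameters
    pp = model.dsca.pep_stream.w_q.weight.data
    hh = model.dsca.hla_stream.w_q.weight.data
    assert not np.array_equal(pp, hh)


def test_cross_stream_gradient_flows(tiny_world):
    """The loss responds to HLA local features through the peptide stream's
    value path (cross-stream information flow)."""
    world, pairs = tiny_world
    cfg = small_model_config(seed=2)
    model = PresentationModel(cfg)
    model.set_training(False)
    feat = Featurizer(cfg)
    batch = feat.prepare(pairs[:4], world.registry)
    probs = model.forward(batch)
    loss = bce_loss(probs, batch.labels)
    loss.backward()
    v_grad = model.dsca.pep_stream.w_v.weight.grad
    assert v_grad is not None and np.abs(v_grad).max() > 0


def test_conventional_mode_runs_end_to_end(tiny_world):
    world, pairs = tiny_world
    cfg = small_model_config(seed=3)
    cfg.dsca.mode = "conventional"
    model = PresentationModel(cfg)
    scores = model.predict_pairs(pairs[:6], world.registry)
    assert scores.shape == (6,)
    assert ((scores > 0) & (scores < 1)).all()
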