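"""Transformer encoder: attention arithmetic, invariants, checkpoints."""

import numpy as np
import pytest

from methylfusion.autodiff import Tensor, no_grad
from methylfusion.encoder import (EncoderConfig, MultiHeadAttention,
                                  TransformerEncoder, encode_batch,
                                  load_pretrained_weights, multi_head_attention,
                                  save_checkpoint)
from methylfusion.tokenization import build_vocabulary, encode_batch_ids


def small_config(**overrides):
    defaults = dict(vocab_size=69, num_blocks=2, d_m=16, num_heads=2,
                    max_positions=20, dropout=0.0, seed=3)
    defaults.update(overrides)
    return EncoderConfig(**defaults)


def naive_attention(x, mha, mask):
    """Triple-loop scaled dot-product attention oracle."""
    L = x.shape[0]
    h, d_k = mha.num_heads, mha.d_k
    wq, bq = mha.w_q.weight.data, mha.w_q.bias.data
    wk, bk = mha.w_k.weight.data, mha.w_k.bias.data
    wv, bv = mha.w_v.weight.data, mha.w_v.bias.data
    heads = []
    for i in range(h):
        sl = slice(i * d_k, (i + 1) * d_k)
        q = x @ wq[:, sl] + bq[sl]
        k = x @ wk[:, sl] + bk[sl]
        v = x @ wv[:, sl] + bv[sl]
        out = np.zeros((L, d_k))
        for a in range(L):
            scores = np.array([q[a] @ k[b] / np.sqrt(d_k) if mask[b] else -np.inf
                               for b in range(L)])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            for b in range(L):
                out[a] += w[b] * v[b]
        heads.append(out)
    return np.concatenate(heads, axis=1) @ mha.w_o.weight.data \
        + mha.w_o.bias.data


def test_attention_matches_triple_loop_oracle(rng):
    """Random L=3, d_m=4, h=2 instance agrees with the naive reference."""
    cfg = EncoderConfig(vocab_size=10, d_m=4, num_heads=2, d_k=2,
                        max_positions=8, dropout=0.0, seed=0)
    mha = MultiHeadAttention(cfg, np.random.default_rng(0))
    x = rng.normal(size=(3, 4)).astype(np.float32)
    mask = np.array([1.0, 1.0, 0.0], dtype=np.float32)
    ours = multi_head_attention(x, mha, mask)
    assert np.allclose(ours, naive_attention(x, mha, mask), atol=1e-6)


def test_single_token_attention_is_value_projection(rng):
    """L=1: softmax over one key is 1, so output = W^O(V projection)."""
    cfg = EncoderConfig(vocab_size=10, d_m=4, num_heads=1, d_k=4,
                        max_positions=8, dropout=0.0, seed=1)
    mha = MultiHeadAttention(cfg, np.random.default_rng(1))
    x = rng.normal(size=(1, 4)).astype(np.float32)
    expected = (x @ mha.w_v.weight.data + mha.w_v.bias.data) \
        @ mha.w_o.weight.data + mha.w_o.bias.data
    assert np.allclose(multi_head_attention(x, mha), expected, atol=1e-6)


def test_attention_rows_stochastic_and_masked_keys_zero(rng):
    cfg = small_config()
    enc = TransformerEncoder(cfg)
    ids = rng.integers(0, 69, size=(4, 12))
    masks = np.ones((4, 12), dtype=np.float32)
    masks[:, 9:] = 0.0
    enc.eval()
    with no_grad():
        enc(ids, masks, store_attention=True)
    attn = enc.last_block_attention
    assert (attn >= 0).all()
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-5)
    assert np.allclose(attn[..., 9:], 0.0, atol=1e-8)  # padded keys ignored


def test_pooled_embeddings_in_tanh_range_and_batch_equivariant(rng):
    enc = TransformerEncoder(small_config())
    ids = rng.integers(0, 69, size=(6, 10))
    masks = np.ones((6, 10), dtype=np.float32)
    pooled, _ = encode_batch(enc, ids, masks)
    assert (np.abs(pooled) < 1.0).all()
    perm = rng.permutation(6)
    permuted, _ = encode_batch(enc, ids[perm], masks[perm])
    assert np.allclose(permuted, pooled[perm], atol=1e-6)


def test_same_seed_eval_runs_bitwise_identical(rng):
    ids = rng.integers(0, 69, size=(3, 10))
    masks = np.ones((3, 10), dtype=np.float32)
    out1, _ = encode_batch(TransformerEncoder(small_config()), ids, masks)
    out2, _ = encode_batch(TransformerEncoder(small_config()), ids, masks)
    assert np.array_equal(out1, out2)


def test_padded_token_ids_do_not_affect_pooled_output(rng):
    enc = TransformerEncoder(small_config())
    ids = rng.integers(0, 69, size=(2, 12))
    masks = np.ones((2, 12), dtype=np.float32)
    masks[:, 8:] = 0.0
    pooled, _ = encode_batch(enc, ids, masks)
    ids2 = ids.copy()
    ids2[:, 8:] = rng.integers(0, 69, size=(2, 4))   # scramble padding ids
    pooled2, _ = encode_batch(enc, ids2, masks)
    assert np.allclose(pooled, pooled2, atol=1e-6)


def numpy_forward(enc: TransformerEncoder, ids, mask):
    """Independent full forward pass in plain NumPy from the state dict."""
    s = enc.state_dict()

    def ln(x, prefix, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * s[f"{prefix}.weight"] \
            + s[f"{prefix}.bias"]

    x = s["token_embedding.weight"][ids] \
        + s["position_embedding.weight"][np.arange(ids.shape[1])]
    x = ln(x, "embedding_norm")
    for b, block in enumerate(enc.blocks):
        attn_out = np.stack([naive_attention(x[i], block.attention, mask[i])
                             for i in range(x.shape[0])])
        x = ln(x + attn_out, f"blocks.{b}.ln1")
        ff = np.maximum(x @ s[f"blocks.{b}.ffn_in.weight"]
                        + s[f"blocks.{b}.ffn_in.bias"], 0.0)
        ff = ff @ s[f"blocks.{b}.ffn_out.weight"] + s[f"blocks.{b}.ffn_out.bias"]
        x = ln(x + ff, f"blocks.{b}.ln2")
    return np.tanh(x[:, 0] @ s["pooler.weight"] + s["pooler.bias"])


def test_encoder_matches_independent_numpy_forward(rng):
    """Full forward (1 block, 1 head) replicated outside the autodiff path."""
    cfg = EncoderConfig(vocab_size=20, num_blocks=1, d_m=8, num_heads=1,
                        max_positions=10, dropout=0.0, seed=5)
    enc = TransformerEncoder(cfg)
    ids = rng.integers(0, 20, size=(3, 6))
    masks = np.ones((3, 6), dtype=np.float32)
    pooled, _ = encode_batch(enc, ids, masks)
    assert np.allclose(pooled, numpy_forward(enc, ids, masks), atol=1e-6)


def test_checkpoint_round_trip_and_mismatch_errors(tmp_path, rng):
    enc = TransformerEncoder(small_config())
    ids = rng.integers(0, 69, size=(2, 10))
    masks = np.ones((2, 10), dtype=np.float32)
    before, _ = encode_batch(enc, ids, masks)
    ckpt = tmp_path / "enc.npz"
    save_checkpoint(enc, ckpt)
    loaded = load_pretrained_weights(ckpt, small_config())
    after, _ = encode_batch(loaded, ids, masks)
    assert np.array_equal(before, after)
    with pytest.raises(ValueError, match="token_embedding.weight"):
        load_pretrained_weights(ckpt, small_config(d_m=8, num_heads=1))
    with pytest.raises(FileNotFoundError):
        load_pretrained_weights(tmp_path / "absent.npz", small_config())


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(vocab_size=10, num_blocks=0)
    with pytest.raises(ValueError):
        EncoderConfig(vocab_size=10, d_m=10, num_heads=3)
    cfg = EncoderConfig.paper_scale(vocab_size=4101)
    assert (cfg.num_blocks, cfg.d_m, cfg.num_heads) == (12, 768, 12)


def test_sequence_longer_than_max_positions_rejected(rng):
    enc = TransformerEncoder(small_config(max_positions=8))
    ids = rng.integers(0, 69, size=(1, 9))
    with pytest.raises(ValueError, match="max_positions"):
        enc(ids, np.ones((1, 9), dtype=np.float32))


def test_encoder_pipeline_from_sequences(rng):
    """Tokenize -> frame -> encode, the path used by the predictor."""
    vocab = build_vocabulary(3)
    seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(4)]
    ids, masks = encode_batch_ids(seqs, 3, vocab, 16)
    enc = TransformerEncoder(small_config())
    pooled, attn = encode_batch(enc, ids, masks, return_attention=True)
    assert pooled.shape == (4, 16)
    assert attn.shape == (4, 2, 16, 16)
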