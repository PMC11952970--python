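"""BERT-style transformer encoder over k-mer token sequences.

Each of the four k-mer views gets its own encoder: an embedding layer
(token + learned absolute position embeddings), a stack of transformer
blocks — multi-head scaled dot-product attention and a feed-forward
sublayer, each wrapped in residual connection + layer normalisation — and
a pooler (dense + Tanh on the [CLS] position) producing one embedding per
sequence. Attention probabilities of the last block are exposed for motif
analysis.

The configuration is size-parametric: the paper-scale geometry (12 blocks,
768-dimensional states, 12 heads) is constructible, while a desk-scale
geometry (2 blocks, 64 dimensions, 2 heads) is the default used throughout
the test suite and synthetic experiments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .layers import Dropout, Embedding, LayerNorm, Linear, Module

_NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Geometry and determinism knobs of one transformer encoder."""

    vocab_size: int
    num_blocks: int = 2
    d_m: int = 64
    num_heads: int = 2
    d_k: int | None = None          # per-head width; default d_m / num_heads
    ffn_dim: int | None = None      # feed-forward hidden width; default 4 * d_m
    max_positions: int = 48
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.num_blocks < 1:
            raise ValueError("num_blocks must be >= 1")
        if self.d_k is None:
            if self.d_m % self.num_heads:
                raise ValueError("d_m must be divisible by num_heads when "
                                 "d_k is not given")
            object.__setattr__(self, "d_k", self.d_m // self.num_heads)
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.d_m)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def paper_scale(cls, vocab_size: int, **overrides) -> "EncoderConfig":
        """The published geometry: 12 blocks, d_m=768, 12 heads."""
        defaults = dict(num_blocks=12, d_m=768, num_heads=12)
        defaults.update(overrides)
        return cls(vocab_size=vocab_size, **defaults)


class MultiHeadAttention(Module):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V per head,
    heads concatenated and mapped back to d_m by W^O."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        h, d_k, d_m = config.num_heads, config.d_k, config.d_m
        self.num_heads, self.d_k = h, d_k
        self.w_q = Linear(d_m, h * d_k, rng)
        self.w_k = Linear(d_m, h * d_k, rng)
        self.w_v = Linear(d_m, h * d_k, rng)
        self.w_o = Linear(h * d_k, d_m, rng)
        self.last_attention: np.ndarray | None = None
        self.store_attention = False

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, _ = x.shape
        h, d_k = self.num_heads, self.d_k

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, d_k).transpose(0, 2, 1, 3)

        q = split_heads(self.w_q(x))
        k = split_heads(self.w_k(x))
        v = split_heads(self.w_v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(d_k))
        # padded keys get -inf so they receive zero attention weight
        bias = (mask.reshape(B, 1, 1, L) - 1.0) * -_NEG_INF
        attn = (scores + Tensor(bias.astype(scores.dtype))).softmax(axis=-1)
        if self.store_attention:
            self.last_attention = attn.data.copy()
        context = attn @ v
        merged = context.transpose(0, 2, 1, 3).reshape(B, L, h * d_k)
        return self.w_o(merged)


def multi_head_attention(x: np.ndarray, mha: MultiHeadAttention,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Functional single-matrix entry point: x is (L, d_m)."""
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"expected an L x d_m matrix, got shape {x.shape}")
    if mask is None:
        mask = np.ones(x.shape[0], dtype=np.float32)
    with no_grad():
        out = mha(Tensor(x[None]), np.asarray(mask, dtype=np.float32)[None])
    return out.data[0]


class TransformerBlock(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.attention = MultiHeadAttention(config, rng)
        self.ln1 = LayerNorm(config.d_m)
        self.ffn_in = Linear(config.d_m, config.ffn_dim, rng)
        self.ffn_out = Linear(config.ffn_dim, config.d_m, rng)
        self.ln2 = LayerNorm(config.d_m)
        self.dropout = Dropout(config.dropout, rng)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.dropout(self.attention(x, mask)))
        ff = self.ffn_out(self.ffn_in(x).relu())
        return self.ln2(x + self.dropout(ff))


class TransformerEncoder(Module):
    """Embedding layer, ``num_blocks`` transformer blocks, [CLS] pooler."""

    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.token_embedding = Embedding(config.vocab_size, config.d_m, rng)
        self.position_embedding = Embedding(config.max_positions, config.d_m, rng)
        self.embedding_norm = LayerNorm(config.d_m)
        self.embedding_dropout = Dropout(config.dropout, rng)
        self.blocks = [TransformerBlock(config, rng)
                       for _ in range(config.num_blocks)]
        self.pooler = Linear(config.d_m, config.d_m, rng)

    def forward(self, ids: np.ndarray, mask: np.ndarray,
                store_attention: bool = False) -> Tensor:
        ids = np.asarray(ids)
        if ids.shape[1] > self.config.max_positions:
            raise ValueError(
                f"sequence length {ids.shape[1]} exceeds max_positions "
                f"{self.config.max_positions}")
        pos = np.arange(ids.shape[1])
        x = self.token_embedding(ids) + self.position_embedding(pos)
        x = self.embedding_dropout(self.embedding_norm(x))
        self.blocks[-1].attention.store_attention = store_attention
        for block in self.blocks:
            block.attention.store_attention = (
                store_attention and block is self.blocks[-1])
            x = block(x, mask)
        cls_state = x[:, 0, :]
        return self.pooler(cls_state).tanh()

    @property
    def last_block_attention(self) -> np.ndarray | None:
        """(batch, heads, L, L) attention of the last block, if stored."""
        return self.blocks[-1].attention.last_attention


def encode_batch(encoder: TransformerEncoder, ids: np.ndarray,
                 masks: np.ndarray, batch_size: int = 256,
                 return_attention: bool = False
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Deterministic (eval-mode, no-grad) encoding of many sequences.

    Returns pooled embeddings (N, d_m) and, optionally, the last-block
    attention tensor (N, heads, L, L).
    """
    encoder.eval()
    pooled, attn = [], []
    with no_grad():
        for start in range(0, len(ids), batch_size):
            sl = slice(start, start + batch_size)
            out = encoder(ids[sl], masks[sl], store_attention=return_attention)
            pooled.append(out.data)
            if return_attention:
                attn.append(encoder.last_block_attention)
    pooled_arr = np.concatenate(pooled, axis=0)
    return pooled_arr, (np.concatenate(attn, axis=0) if return_attention else None)


def save_checkpoint(encoder: TransformerEncoder, path: str | Path) -> None:
    """Write weights as an .npz key->tensor archive with the config beside it."""
    path = Path(path)
    np.savez(path, **encoder.state_dict())
    path.with_suffix(".config.json").write_text(
        json.dumps(encoder.config.to_dict(), indent=2))


def load_pretrained_weights(path: str | Path,
                            config: EncoderConfig) -> TransformerEncoder:
    """Build an encoder from ``config`` and load an .npz checkpoint into it.

    Shape mismatches raise with the offending parameter name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    encoder = TransformerEncoder(config)
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    encoder.load_state_dict(state)
    return encoder
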