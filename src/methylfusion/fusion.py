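"""Multi-view representation fusion.

The four per-k embeddings of a sequence are views of one underlying object.
Fusion has two parts:

* A *decoding part* learns, for the training set only, a free auxiliary
  comprehensive representation ẑ_n per sample together with per-view
  relation matrices W^v and decoder networks g^v, by minimising the
  reconstruction objective

      L_r = (1/N) Σ_v Σ_n ||x_n^v − g^v(ẑ_n W^v)||²  +  β Σ_v ||W^v||_{2,1}.

  The L2,1 penalty (sum of row norms) drives whole rows of W^v to zero,
  separating dimensions of ẑ that are consistent across views from
  complementary, view-specific ones.

* An *encoding part* maps any sample — including out-of-sample test
  sequences — to the comprehensive representation z_n = (1/V) Σ_v f^v(x_n^v),
  where each encoder f^v carries batch normalisation in every layer. The
  encoders are guided toward the auxiliary solution through an annealed
  alignment loss L_a = mean ||z_n − ẑ_n||² + γ Σ_v ||w^v − σ(a w̄^v + b)||²,
  where w^v is the final BN weight vector of f^v and w̄^v is the column-mean
  of |W^v|; a and b are trainable scalars and σ the logistic sigmoid.

The training objective of the second stage combines cross-entropy,
δ(t)·L_a with δ(t) = max(0, 1 − t/10), and an L1 penalty λ2 Σ_v ||w^v||_1
on the raw BN weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor
from .layers import BatchNorm1d, Linear, Module, cross_entropy

__all__ = [
    "FusionConfig", "FusionModule", "ViewEncoder", "ViewDecoder",
    "l21_norm", "reconstruction_loss", "alignment_loss", "bn_weight_penalty",
    "annealing_delta",
]


# ---------------------------------------------------------------------------
# pure loss arithmetic (dtype follows the inputs; float64 in oracle tests)
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def l21_norm(W) -> float:
    """Sum over rows of each row's Euclidean norm (structured sparsity)."""
    data = W.data if isinstance(W, Tensor) else np.asarray(W)
    if not np.all(np.isfinite(data)):
        raise ValueError("L2,1 norm requires finite entries")
    return float(np.sqrt((data * data).sum(axis=1)).sum())


def reconstruction_loss(x_views, xhat_views) -> Tensor:
    """(1/N) Σ_v Σ_n ||x_n^v − x̂_n^v||² — mean over samples, sum over views."""
    if len(x_views) == 0 or len(x_views) != len(xhat_views):
        raise ValueError("need one reconstruction per view")
    x_views = [_as_tensor(x) for x in x_views]
    xhat_views = [_as_tensor(x) for x in xhat_views]
    n = x_views[0].shape[0]
    if n == 0:
        raise ValueError("empty batch")
    total = None
    for x, xhat in zip(x_views, xhat_views):
        diff = x - xhat
        term = (diff * diff).sum()
        total = term if total is None else total + term
    return total * (1.0 / n)


def alignment_loss(z, z_hat) -> Tensor:
    """mean_n ||z_n − ẑ_n||² between fused and auxiliary representations."""
    z, z_hat = _as_tensor(z), _as_tensor(z_hat)
    diff = z - z_hat
    return (diff * diff).sum() * (1.0 / z.shape[0])


def bn_weight_penalty(w, W, a, b) -> Tensor:
    """||w − σ(a·w̄ + b)||² with w̄ = column-mean of |W| (length d)."""
    w, a, b = _as_tensor(w), _as_tensor(a), _as_tensor(b)
    W = _as_tensor(W)
    d = W.shape[0]
    if w.shape[0] != d:
        raise ValueError(
            f"BN weight length {w.shape[0]} does not match relation-matrix "
            f"row count {d}")
    h_dec = W.shape[1]
    w_bar = W.abs().sum(axis=1) * (1.0 / h_dec)
    target = (w_bar * a + b).sigmoid()
    diff = w - target
    return (diff * diff).sum()


def annealing_delta(t: int) -> float:
    """δ(t) = max(0, 1 − t/10): phases out the alignment loss by epoch 10."""
    if t < 0:
        raise ValueError(f"epoch index must be non-negative, got {t}")
    return max(0.0, 1.0 - t / 10.0)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of the fusion module.

    beta weighs the L2,1 structured-sparsity penalty of the decoding part;
    gamma the BN-weight guidance inside L_a; lambda1 the cross-entropy and
    lambda2 the L1 sparsity term of the stage-2 objective. d is the
    comprehensive-representation width, h_dec the relation-matrix hidden
    width.
    """

    n_views: int = 4
    embed_dim: int = 64
    d: int = 128
    h_dec: int = 64
    hidden_dim: int | None = None   # MLP hidden width; default d
    beta: float = 0.1
    gamma: float = 0.1
    lambda1: float = 1.0
    lambda2: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim is None:
            object.__setattr__(self, "hidden_dim", self.d)
        for name in ("beta", "gamma", "lambda1", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ViewDecoder(Module):
    """g^v: two-layer ReLU perceptron from ẑW^v (h_dec) back to the view."""

    def __init__(self, h_dec: int, hidden: int, embed_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(h_dec, hidden, rng)
        self.fc2 = Linear(hidden, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class ViewEncoder(Module):
    """f^v: two-layer perceptron with batch normalisation in every layer."""

    def __init__(self, embed_dim: int, hidden: int, d: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(embed_dim, hidden, rng)
        self.bn1 = BatchNorm1d(hidden)
        self.fc2 = Linear(hidden, d, rng)
        self.bn2 = BatchNorm1d(d)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn2(self.fc2(self.bn1(self.fc1(x)).relu()))

    @property
    def final_bn_weight(self) -> Parameter:
        """w^v — the weight vector of the last BN layer (length d)."""
        return self.bn2.weight


class FusionModule(Module):
    """Relation matrices, decoders, encoders and the auxiliary ẑ table."""

    def __init__(self, config: FusionConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.relation_matrices = [
            Parameter(rng.normal(0.0, 0.1, size=(c.d, c.h_dec))
                      .astype(np.float32))
            for _ in range(c.n_views)]
        self.decoders = [ViewDecoder(c.h_dec, c.hidden_dim, c.embed_dim, rng)
                         for _ in range(c.n_views)]
        self.encoders = [ViewEncoder(c.embed_dim, c.hidden_dim, c.d, rng)
                         for _ in range(c.n_views)]
        self.a = Parameter(np.array(1.0, dtype=np.float32))
        self.b = Parameter(np.array(0.0, dtype=np.float32))
        self.z_hat: Parameter | None = None
        self._z_rng = rng

    # -- auxiliary representations --------------------------------------
    def init_auxiliary(self, n_train: int) -> Parameter:
        """One free ẑ_n per training sample, N(0, 0.1) initialised."""
        self.z_hat = Parameter(
            self._z_rng.normal(0.0, 0.1, size=(n_train, self.config.d))
            .astype(np.float32))
        return self.z_hat

    def _require_z_hat(self, indices: np.ndarray) -> Tensor:
        if self.z_hat is None:
            raise ValueError("auxiliary representations not initialised; "
                             "run stage 1 (init_auxiliary) first")
        indices = np.asarray(indices)
        if indices.max(initial=-1) >= self.z_hat.shape[0] or \
                indices.min(initial=0) < 0:
            raise ValueError("sample index without an auxiliary ẑ_n "
                             "(test samples never carry one)")
        return self.z_hat[indices]

    def _check_views(self, x_views) -> list[Tensor]:
        if len(x_views) != self.config.n_views:
            raise ValueError(
                f"expected {self.config.n_views} views, got {len(x_views)}")
        return [_as_tensor(x) for x in x_views]

    # -- decoding part ---------------------------------------------------
    def reconstruct(self, z_hat_batch, view: int) -> Tensor:
        """x̂^v = g^v(ẑ W^v)."""
        z = _as_tensor(z_hat_batch)
        return self.decoders[view](z @ self.relation_matrices[view])

    def reconstruction_loss(self, x_views, indices: np.ndarray) -> Tensor:
        x_views = self._check_views(x_views)
        z = self._require_z_hat(indices)
        xhat = [self.reconstruct(z, v) for v in range(self.config.n_views)]
        return reconstruction_loss(x_views, xhat)

    def decoding_objective(self, x_views, indices: np.ndarray) -> float:
        """L_r + β Σ_v ||W^v||_{2,1}, as a plain number (for monitoring)."""
        lr = self.reconstruction_loss(x_views, indices).item()
        penalty = sum(l21_norm(W) for W in self.relation_matrices)
        return lr + self.config.beta * penalty

    # -- encoding part ---------------------------------------------------
    def encode_views(self, x_views) -> list[Tensor]:
        """Per-view aligned representations z_n^v = f^v(x_n^v)."""
        x_views = self._check_views(x_views)
        return [enc(x) for enc, x in zip(self.encoders, x_views)]

    def fuse(self, x_views) -> Tensor:
        """z_n = (1/V) Σ_v f^v(x_n^v); valid for train and test samples."""
        zs = self.encode_views(x_views)
        total = zs[0]
        for z in zs[1:]:
            total = total + z
        return total * (1.0 / self.config.n_views)

    def bn_weight_penalty(self, view: int) -> Tensor:
        return bn_weight_penalty(self.encoders[view].final_bn_weight,
                                 self.relation_matrices[view],
                                 self.a, self.b)

    def auxiliary_loss(self, x_views, indices: np.ndarray,
                       z: Tensor | None = None) -> Tensor:
        """L_a: alignment to ẑ plus γ × BN-weight guidance over all views."""
        z_hat = self._require_z_hat(indices)
        if z is None:
            z = self.fuse(x_views)
        loss = alignment_loss(z, z_hat)
        if self.config.gamma > 0:
            penalty = self.bn_weight_penalty(0)
            for v in range(1, self.config.n_views):
                penalty = penalty + self.bn_weight_penalty(v)
            loss = loss + self.config.gamma * penalty
        return loss

    def sparsity_term(self) -> Tensor:
        """Σ_v Σ_i |w_i^v| on the raw final-BN weight vectors."""
        total = self.encoders[0].final_bn_weight.abs().sum()
        for enc in self.encoders[1:]:
            total = total + enc.final_bn_weight.abs().sum()
        return total

    def total_objective(self, logits: Tensor, labels: np.ndarray,
                        x_views, indices: np.ndarray, t: int,
                        z: Tensor | None = None) -> Tensor:
        """λ1·CE + δ(t)·L_a + λ2·Σ_v||w^v||_1 (stage-2 objective)."""
        c = self.config
        loss = c.lambda1 * cross_entropy(logits, labels)
        delta = annealing_delta(t)
        if delta > 0:
            loss = loss + delta * self.auxiliary_loss(x_views, indices, z=z)
        if c.lambda2 > 0:
            loss = loss + c.lambda2 * self.sparsity_term()
        return loss

    # -- parameter groups -------------------------------------------------
    def decoding_parameters(self) -> list[Parameter]:
        """Stage-1 trainables: {W^v, g^v, ẑ} (ẑ must be initialised)."""
        params = list(self.relation_matrices)
        for dec in self.decoders:
            params.extend(dec.parameters())
        if self.z_hat is not None:
            params.append(self.z_hat)
        return params

    def encoding_parameters(self) -> list[Parameter]:
        """Stage-2 fusion trainables: {f^v, a, b}."""
        params: list[Parameter] = []
        for enc in self.encoders:
            params.extend(enc.parameters())
        params.extend([self.a, self.b])
        return params
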