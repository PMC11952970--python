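"""Fusion module: loss arithmetic vs loop oracles, alignment behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylfusion.autodiff import Tensor
from methylfusion.fusion import (FusionConfig, FusionModule, alignment_loss,
                                 annealing_delta, bn_weight_penalty, l21_norm,
                                 reconstruction_loss)


def make_module(n_views=2, embed_dim=6, d=4, h_dec=3, **kwargs):
    cfg = FusionConfig(n_views=n_views, embed_dim=embed_dim, d=d,
                       h_dec=h_dec, seed=9, **kwargs)
    return FusionModule(cfg)


# -- L2,1 norm --------------------------------------------------------------

def test_l21_norm_worked_examples():
    assert l21_norm(np.zeros((3, 4))) == 0.0
    assert l21_norm(np.array([[3.0, 4.0]])) == 5.0


def test_l21_norm_matches_elementwise_oracle(rng):
    W = rng.normal(size=(5, 3))
    brute = sum(np.sqrt(sum(W[i, j] ** 2 for j in range(3))) for i in range(5))
    assert abs(l21_norm(W) - brute) < 1e-10


@given(c=st.floats(-10, 10, allow_nan=False))
def test_l21_norm_homogeneity(c):
    W = np.arange(6, dtype=float).reshape(3, 2)
    assert np.isclose(l21_norm(c * W), abs(c) * l21_norm(W), atol=1e-9)


def test_l21_norm_rejects_non_finite():
    with pytest.raises(ValueError):
        l21_norm(np.array([[np.inf, 1.0]]))


# -- decoding part ----------------------------------------------------------

def test_reconstruct_nullspace_and_shape(rng):
    fm = make_module()
    fm.relation_matrices[0].data[:] = 0.0
    z = Tensor(rng.normal(size=(3, 4)))
    out = fm.reconstruct(z, 0)
    assert out.shape == (3, 6)
    # W^v = 0 makes the reconstruction constant across samples: g^v(0)
    assert np.allclose(out.data[0], out.data[1], atol=1e-7)
    assert np.allclose(out.data[0], out.data[2], atol=1e-7)


def test_reconstruct_matches_hand_multiplication():
    """Linear decoder (identity layers) so x̂ = relu(ẑ W) exactly."""
    fm = make_module(n_views=1, embed_dim=2, d=2, h_dec=2, hidden_dim=2)
    W = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)
    fm.relation_matrices[0].data[:] = W
    dec = fm.decoders[0]
    dec.fc1.weight.data[:] = np.eye(2)
    dec.fc1.bias.data[:] = 0.0
    dec.fc2.weight.data[:] = np.eye(2)
    dec.fc2.bias.data[:] = 0.0
    z = np.array([[1.0, 1.0]])
    assert np.allclose(fm.reconstruct(Tensor(z), 0).data, z @ W, atol=1e-6)


def test_reconstruction_loss_examples_and_loop_oracle(rng):
    assert reconstruction_loss([np.ones((2, 3))], [np.ones((2, 3))]).item() == 0.0
    unit = reconstruction_loss([np.array([[1.0, 0.0]])],
                               [np.array([[0.0, 0.0]])])
    assert unit.item() == 1.0
    x = [rng.normal(size=(4, 3)) for _ in range(2)]
    xh = [rng.normal(size=(4, 3)) for _ in range(2)]
    brute = sum(np.sum((x[v][n] - xh[v][n]) ** 2)
                for v in range(2) for n in range(4)) / 4
    assert abs(reconstruction_loss(x, xh).item() - brute) < 1e-10


def test_reconstruction_loss_rejects_empty_batch():
    with pytest.raises(ValueError):
        reconstruction_loss([np.zeros((0, 2))], [np.zeros((0, 2))])


def test_decoding_objective_composition(rng):
    fm = make_module(beta=0.7)
    fm.init_auxiliary(5)
    x = [rng.normal(size=(5, 6)).astype(np.float32) for _ in range(2)]
    idx = np.arange(5)
    lr = fm.reconstruction_loss(x, idx).item()
    penalty = sum(l21_norm(W) for W in fm.relation_matrices)
    assert np.isclose(fm.decoding_objective(x, idx), lr + 0.7 * penalty,
                      rtol=1e-10)
    fm0 = make_module(beta=0.0)
    fm0.init_auxiliary(5)
    assert np.isclose(fm0.decoding_objective(x, idx),
                      fm0.reconstruction_loss(x, idx).item(), rtol=1e-10)


# -- encoding part ----------------------------------------------------------

def test_fuse_is_mean_of_view_encoders(rng):
    fm = make_module(n_views=4)
    fm.eval()
    x = [rng.normal(size=(3, 6)).astype(np.float32) for _ in range(4)]
    zs = [z.data for z in fm.encode_views(x)]
    assert np.allclose(fm.fuse(x).data, np.mean(zs, axis=0), atol=1e-10)


def test_fuse_single_view_and_identical_views(rng):
    fm1 = make_module(n_views=1)
    fm1.eval()
    x = rng.normal(size=(3, 6)).astype(np.float32)
    assert np.allclose(fm1.fuse([x]).data, fm1.encoders[0](Tensor(x)).data)
    fm = make_module(n_views=3)
    fm.eval()
    shared = fm.encoders[0].state_dict()
    for enc in fm.encoders[1:]:
        enc.load_state_dict(shared)
    assert np.allclose(fm.fuse([x, x, x]).data,
                       fm.encoders[0](Tensor(x)).data, atol=1e-6)


def test_fuse_rejects_missing_view(rng):
    fm = make_module(n_views=2)
    with pytest.raises(ValueError, match="views"):
        fm.fuse([rng.normal(size=(3, 6))])


def test_bn_weight_penalty_zero_at_target_and_hand_case():
    W = np.array([[1.0, -2.0], [0.5, 0.5]])
    w_bar = np.abs(W).mean(axis=1)
    target = 1.0 / (1.0 + np.exp(-(1.0 * w_bar + 0.0)))
    assert bn_weight_penalty(target, W, 1.0, 0.0).item() < 1e-15
    # hand-set 2-dim case, a=1, b=0
    w = np.array([0.9, 0.1])
    expected = np.sum((w - target) ** 2)
    assert abs(bn_weight_penalty(w, W, 1.0, 0.0).item() - expected) < 1e-12
    assert bn_weight_penalty(np.array([5.0, -3.0]), W, 2.0, 1.0).item() >= 0.0


def test_bn_weight_penalty_dimension_mismatch():
    with pytest.raises(ValueError, match="match"):
        bn_weight_penalty(np.ones(3), np.ones((2, 2)), 1.0, 0.0)


def test_auxiliary_loss_cases_and_loop_oracle(rng):
    fm = make_module(gamma=0.0)
    fm.eval()
    x = [rng.normal(size=(4, 6)).astype(np.float32) for _ in range(2)]
    fm.init_auxiliary(4)
    z = fm.fuse(x)
    fm.z_hat.data[:] = z.data          # perfect alignment, gamma=0 -> 0
    assert fm.auxiliary_loss(x, np.arange(4)).item() < 1e-12

    fm2 = make_module(gamma=0.3)
    fm2.eval()
    fm2.init_auxiliary(4)
    idx = np.arange(4)
    z2 = fm2.fuse(x).data.astype(np.float64)
    zh = fm2.z_hat.data.astype(np.float64)
    brute = np.mean([np.sum((z2[n] - zh[n]) ** 2) for n in range(4)])
    for v in range(2):
        W = fm2.relation_matrices[v].data.astype(np.float64)
        w = fm2.encoders[v].final_bn_weight.data.astype(np.float64)
        w_bar = np.abs(W).mean(axis=1)
        sig = 1.0 / (1.0 + np.exp(-(fm2.a.item() * w_bar + fm2.b.item())))
        brute += 0.3 * np.sum((w - sig) ** 2)
    assert abs(fm2.auxiliary_loss(x, idx).item() - brute) < 1e-6


def test_auxiliary_loss_requires_z_hat(rng):
    fm = make_module()
    x = [rng.normal(size=(2, 6)) for _ in range(2)]
    with pytest.raises(ValueError, match="stage 1|auxiliary"):
        fm.auxiliary_loss(x, np.arange(2))
    fm.init_auxiliary(2)
    with pytest.raises(ValueError, match="auxiliary"):
        fm.auxiliary_loss(x, np.array([0, 5]))    # index beyond training set


# -- annealing and total objective ------------------------------------------

@pytest.mark.parametrize("t,expected", [(0, 1.0), (5, 0.5), (10, 0.0),
                                        (15, 0.0)])
def test_annealing_delta_values(t, expected):
    assert annealing_delta(t) == expected


def test_annealing_delta_monotone_and_rejects_negative():
    deltas = [annealing_delta(t) for t in range(21)]
    assert all(a >= b for a, b in zip(deltas, deltas[1:]))
    assert deltas[0] == 1.0 and all(d == 0.0 for d in deltas[10:])
    with pytest.raises(ValueError):
        annealing_delta(-1)


def test_total_objective_degenerate_and_composition(rng):
    fm = make_module(lambda1=0.0, lambda2=0.0)
    fm.eval()
    fm.init_auxiliary(4)
    x = [rng.normal(size=(4, 6)).astype(np.float32) for _ in range(2)]
    logits = Tensor(rng.normal(size=(4, 2)))
    labels = np.array([0, 1, 0, 1])
    # all three terms vanish: lambda1 = lambda2 = 0 and delta(12) = 0
    assert fm.total_objective(logits, labels, x, np.arange(4), t=12).item() == 0.0

    fm2 = make_module(lambda1=0.5, lambda2=0.2, gamma=0.1)
    fm2.eval()
    fm2.init_auxiliary(4)
    from methylfusion.layers import cross_entropy
    ce = cross_entropy(logits, labels).item()
    la = fm2.auxiliary_loss(x, np.arange(4)).item()
    sparse = sum(np.abs(e.final_bn_weight.data).sum() for e in fm2.encoders)
    total = fm2.total_objective(logits, labels, x, np.arange(4), t=0).item()
    assert np.isclose(total, 0.5 * ce + 1.0 * la + 0.2 * sparse, rtol=1e-5)


def test_stage2_alignment_component_decreases_when_isolated():
    """With classification switched off (lambda1 = 0) the stage-2 objective
    is the annealed alignment loss; dividing each epoch's training loss by
    delta(t) must reveal a decreasing L_a — the guidance toward ẑ works."""
    from methylfusion.simulate import GeneratorConfig, generate_dataset
    from methylfusion.training import MethylationPredictor, TrainConfig
    from methylfusion.fusion import FusionConfig

    ds = generate_dataset(GeneratorConfig(n_pos=100, n_neg=100, seed=1))
    model = MethylationPredictor(
        encoder_config=dict(num_blocks=2, d_m=64, num_heads=2),
        fusion_config=FusionConfig(d=64, h_dec=32, embed_dim=64,
                                   lambda1=0.0),
        train_config=TrainConfig(seed=1, stage1_lr=1e-3,
                                 lr_fusion_head=1e-3, lr_encoder=1e-4))
    views, _ = model.view_embeddings(ds.sequences)
    model.train_stage1(view_embeddings=views, epochs=200)
    trace = model.train_stage2(ds.sequences, ds.labels, epochs=6).loss_trace
    la = [loss / annealing_delta(t) for t, loss in enumerate(trace)]
    assert la[-1] < la[0]
    assert all(trace[i + 1] < trace[i] for i in range(len(trace) - 1))
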