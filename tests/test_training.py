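"""Two-stage protocol, fine-tuning, prediction and cross-species plumbing."""

import numpy as np
import pytest

from conftest import tiny_predictor
from methylfusion import (GeneratorConfig, TrainConfig, generate_dataset,
                          train_test_split)
from methylfusion.training import cross_species_matrix, pool_datasets


@pytest.fixture(scope="module")
def micro_data():
    ds = generate_dataset(GeneratorConfig(n_pos=60, n_neg=60, seed=13))
    return train_test_split(ds, 0.8, 13)


def param_checksums(module):
    return {name: float(p.data.sum()) for name, p in module.named_parameters()}


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(stage1_lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(stage2_epochs=-1)


def test_stage1_zero_epochs_is_noop(micro_data):
    train, _ = micro_data
    model = tiny_predictor(seed=1)
    before = [W.data.copy() for W in model.fusion.relation_matrices]
    model.train_stage1(train_sequences=train.sequences, epochs=0)
    for W, orig in zip(model.fusion.relation_matrices, before):
        assert np.array_equal(W.data, orig)


def test_stage1_reduces_objective_and_freezes_rest(micro_data):
    train, _ = micro_data
    model = tiny_predictor(seed=1)
    enc_sums = {k: param_checksums(model.encoders[k]) for k in model.ks}
    clf_sums = param_checksums(model.classifier)
    state = model.train_stage1(train_sequences=train.sequences, epochs=25)
    assert state.loss_trace[-1] < state.loss_trace[0]
    assert len(state.loss_trace) == 26            # init + one per epoch
    for k in model.ks:
        assert param_checksums(model.encoders[k]) == enc_sums[k]
    assert param_checksums(model.classifier) == clf_sums
    # one auxiliary vector per training sample, none for test samples
    assert model.fusion.z_hat.shape == (len(train), 64)


def test_stage1_rerun_reproduces_trace(micro_data):
    train, _ = micro_data
    traces = []
    for _ in range(2):
        model = tiny_predictor(seed=4)
        st = model.train_stage1(train_sequences=train.sequences, epochs=5)
        traces.append(st.loss_trace)
    assert np.allclose(traces[0], traces[1], atol=1e-6)


def test_stage2_requires_stage1(micro_data):
    train, _ = micro_data
    model = tiny_predictor(seed=1)
    with pytest.raises(ValueError, match="stage1"):
        model.train_stage2(train.sequences, train.labels, epochs=1)


def test_end_to_end_micro_run_is_reproducible(micro_data):
    """Same seed, same data: final test metrics agree to 1e-6."""
    train, test = micro_data
    accs, traces = [], []
    for _ in range(2):
        model = tiny_predictor(seed=3)
        model.fit(train, fine_tune_sets=[train], fine_tune_epochs=1,
                  stage1_epochs=3, stage2_epochs=2)
        accs.append(model.evaluate(test).acc)
        traces.append(model.history[-1].loss_trace)
    assert abs(accs[0] - accs[1]) < 1e-6
    assert np.allclose(traces[0], traces[1], atol=1e-6)


def test_training_reaches_high_accuracy_on_separable_data(e2e_run):
    """Planted-motif classes are separable; training ACC should be >= 0.95."""
    model, train, _, _ = e2e_run
    train_report = model.evaluate(train)
    assert train_report.acc >= 0.95
    # delta is zero from epoch 10 on, so stage-2 ran with annealing complete
    from methylfusion.fusion import annealing_delta
    assert annealing_delta(12) == 0.0


def test_predictions_are_probabilities_and_deterministic(micro_data, e2e_run):
    model, _, test, _ = e2e_run
    seqs = test.sequences[:8] + test.sequences[:8]   # duplicates
    probs = model.predict_proba(seqs)
    assert ((probs >= 0) & (probs <= 1)).all()
    assert np.allclose(probs[:8], probs[8:], atol=1e-12)
    labels = model.predict(seqs)
    assert np.array_equal(labels, (probs >= 0.5).astype(int))


def test_sequence_length_mismatch_rejected(e2e_run):
    model = e2e_run[0]
    with pytest.raises(ValueError, match="length"):
        model.predict_proba(["ACGT" * 5])


def test_pool_datasets_sizes_and_length_check(micro_data):
    train, test = micro_data
    pooled = pool_datasets([train, test])
    assert len(pooled) == len(train) + len(test)
    short = generate_dataset(GeneratorConfig(n_pos=5, n_neg=5, length=21,
                                             motif_start=5, seed=0))
    with pytest.raises(ValueError, match="length"):
        pool_datasets([train, short])


def test_fine_tune_selects_best_checkpoint(micro_data):
    train, test = micro_data
    model = tiny_predictor(seed=5, fine_tune_epochs=3)
    states = model.fine_tune_multispecies([train], epochs=3)
    for k, st in states.items():
        accs = [m["ACC"] for m in st.metric_trace]
        assert st.best_metric == max(accs)        # argmax contract
        assert st.best_epoch == int(np.argmax(accs))
        assert len(st.loss_trace) == 3


def test_fine_tune_paper_protocol_uses_test_split(micro_data):
    train, test = micro_data
    model = tiny_predictor(seed=5, paper_protocol=True)
    states = model.fine_tune_multispecies([train], eval_sets=[test], epochs=2)
    assert all(len(s.metric_trace) == 2 for s in states.values())


def test_cross_species_identity_and_matrix_shape(micro_data):
    train, test = micro_data
    model = tiny_predictor(seed=2)
    # untrained model still yields a valid report; A=B is plain evaluation
    report = model.cross_species_evaluate(test)
    assert report.counts.total == len(test)
    assert report.as_dict() == model.evaluate(test).as_dict()

    pairs = [(train, test)] * 3
    accs = cross_species_matrix(pairs, lambda i, tr: tiny_predictor(seed=i))
    assert accs.shape == (3, 3)


def test_model_save_load_round_trip(tmp_path, micro_data):
    train, test = micro_data
    model = tiny_predictor(seed=6)
    model.train_stage1(train_sequences=train.sequences, epochs=2)
    model.train_stage2(train.sequences, train.labels, epochs=1)
    probs = model.predict_proba(test.sequences)
    model.save(tmp_path / "model")
    from methylfusion import MethylationPredictor
    loaded = MethylationPredictor.load(tmp_path / "model")
    assert np.allclose(loaded.predict_proba(test.sequences), probs, atol=1e-7)
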