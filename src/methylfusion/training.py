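"""Model assembly and the two-stage training protocol.

A predictor holds one transformer encoder per k-mer view (k = 3..6 by
default), the fusion module, and a two-layer classification head. Training
follows the published protocol:

* optional fine-tuning of each view encoder on a (possibly multi-species
  pooled) dataset with a temporary dense head, keeping the epoch checkpoint
  with the highest evaluation accuracy;
* stage 1 — the fusion module's decoding part ({W^v, g^v, ẑ_n}) is trained
  alone on cached view embeddings with SGD (lr 5e-5, weight decay 3e-3);
  the L2,1 penalty is applied through its proximal operator so whole rows
  of W^v can reach exactly zero;
* stage 2 — the whole model trains end-to-end with AdamW under the combined
  objective λ1·CE + δ(t)·L_a + λ2·Σ_v||w^v||_1, with two parameter groups:
  the pre-trained encoders at (lr 3e-5, wd 1e-3) and the freshly
  initialised fusion encoders + classifier at (lr 5e-5, wd 3e-3).
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import no_grad
from .encoder import EncoderConfig, TransformerEncoder, encode_batch
from .fusion import FusionConfig, FusionModule, annealing_delta
from .layers import Linear, Module, cross_entropy
from .metrics import MetricsReport, evaluate_predictions
from .optim import SGD, AdamW, prox_l21_
from .simulate import LabeledDataset, SequenceRecord
from .tokenization import DEFAULT_KS, build_vocabulary, encode_batch_ids

__all__ = ["TrainConfig", "TrainState", "MethylationPredictor",
           "pool_datasets", "cross_species_matrix"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule for all three phases."""

    # stage 1: decoding part, SGD
    stage1_epochs: int = 50
    stage1_batch_size: int = 128
    stage1_lr: float = 5e-5
    stage1_weight_decay: float = 3e-3
    # stage 2: whole model, AdamW, two parameter groups
    stage2_epochs: int = 10
    stage2_batch_size: int = 32
    lr_encoder: float = 3e-5
    weight_decay_encoder: float = 1e-3
    lr_fusion_head: float = 5e-5
    weight_decay_fusion_head: float = 3e-3
    # encoder fine-tuning with a temporary dense head
    fine_tune_epochs: int = 20
    fine_tune_batch_size: int = 32
    fine_tune_lr: float = 1e-4
    fine_tune_weight_decay: float = 1e-3
    val_fraction: float = 0.1
    paper_protocol: bool = False   # select fine-tune checkpoint on the test set
    seed: int = 0

    def __post_init__(self):
        for name in ("stage1_lr", "stage1_weight_decay", "lr_encoder",
                     "weight_decay_encoder", "lr_fusion_head",
                     "weight_decay_fusion_head", "fine_tune_lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("stage1_epochs", "stage2_epochs", "fine_tune_epochs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainState:
    """Per-phase traces; loss trace length equals completed epochs."""

    stage: str
    loss_trace: list[float] = field(default_factory=list)
    metric_trace: list[dict] = field(default_factory=list)
    best_epoch: int | None = None
    best_metric: float | None = None


class Classifier(Module):
    """Two fully connected layers mapping z_n to 2-class logits."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d, max(d // 2, 8), rng)
        self.fc2 = Linear(max(d // 2, 8), 2, rng)

    def forward(self, z):
        return self.fc2(self.fc1(z).relu())


class _FineTuneHead(Module):
    """Temporary dense head used only while fine-tuning one encoder."""

    def __init__(self, d_m: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(d_m, 2, rng)

    def forward(self, pooled):
        return self.fc(pooled)


def pool_datasets(datasets: list[LabeledDataset],
                  name: str = "pooled") -> LabeledDataset:
    """Concatenate several datasets (multi-species pooling)."""
    if not datasets:
        raise ValueError("need at least one dataset to pool")
    lengths = {ds.length for ds in datasets}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent sequence lengths across datasets: "
                         f"{sorted(lengths)}")
    records: list[SequenceRecord] = []
    for ds in datasets:
        for r in ds.records:
            records.append(dataclasses.replace(r, id=f"{ds.name}:{r.id}"))
    return LabeledDataset(records=tuple(records), name=name)


class MethylationPredictor:
    """Multi-view methylation site predictor."""

    def __init__(self, ks: tuple[int, ...] = DEFAULT_KS,
                 sequence_length: int = 41,
                 encoder_config: dict | None = None,
                 fusion_config: FusionConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.ks = tuple(ks)
        self.sequence_length = sequence_length
        self.train_config = train_config or TrainConfig()
        seed = self.train_config.seed
        enc_kwargs = dict(encoder_config or {})
        enc_kwargs.setdefault("max_positions", sequence_length + 2)
        self.vocabs = {k: build_vocabulary(k) for k in self.ks}
        self.encoder_configs = {
            k: EncoderConfig(vocab_size=len(self.vocabs[k]),
                             seed=seed + 17 * k, **enc_kwargs)
            for k in self.ks}
        self.encoders = {k: TransformerEncoder(self.encoder_configs[k])
                         for k in self.ks}
        d_m = next(iter(self.encoder_configs.values())).d_m
        fc = fusion_config or FusionConfig()
        if fc.n_views != len(self.ks) or fc.embed_dim != d_m:
            fc = dataclasses.replace(fc, n_views=len(self.ks), embed_dim=d_m)
        self.fusion = FusionModule(dataclasses.replace(fc, seed=seed + 101))
        self.classifier = Classifier(fc.d, np.random.default_rng(seed + 202))
        self.history: list[TrainState] = []
        self._encoded_cache: dict | None = None

    # -- plumbing --------------------------------------------------------
    def _check_length(self, sequences: list[str]) -> None:
        bad = {len(s) for s in sequences} - {self.sequence_length}
        if bad:
            raise ValueError(
                f"sequences of length {sorted(bad)} are incompatible with "
                f"the model's training length {self.sequence_length}")

    def encode_inputs(self, sequences: list[str]) -> dict[int, tuple]:
        """Token ids + masks per view; framed length is L - k + 3."""
        self._check_length(sequences)
        out = {}
        for k in self.ks:
            max_len = self.sequence_length - k + 3
            out[k] = encode_batch_ids(sequences, k, self.vocabs[k], max_len)
        return out

    def view_embeddings(self, sequences: list[str],
                        return_attention: bool = False
                        ) -> tuple[dict[int, np.ndarray], dict[int, tuple] | None]:
        """Deterministic (eval-mode) pooled embeddings for each view."""
        encoded = self.encode_inputs(sequences)
        views, attn = {}, {}
        for k in self.ks:
            ids, masks = encoded[k]
            pooled, att = encode_batch(self.encoders[k], ids, masks,
                                       return_attention=return_attention)
            views[k] = pooled
            if return_attention:
                attn[k] = (att, masks)
        return views, (attn if return_attention else None)

    # -- fine-tuning -----------------------------------------------------
    def fine_tune_multispecies(self, train_sets: list[LabeledDataset],
                               eval_sets: list[LabeledDataset] | None = None,
                               epochs: int | None = None) -> dict[int, TrainState]:
        """Fine-tune every view encoder on the pooled training splits.

        The per-epoch checkpoint with the highest evaluation ACC is kept.
        Evaluation uses a held-out fraction carved from the pooled training
        split, or — with ``paper_protocol`` and ``eval_sets`` given — the
        pooled test split (optimistic: test-set checkpoint selection).
        """
        cfg = self.train_config
        epochs = cfg.fine_tune_epochs if epochs is None else epochs
        pooled = pool_datasets(train_sets)
        rng = np.random.default_rng(cfg.seed + 301)
        if cfg.paper_protocol and eval_sets:
            train_ds = pooled
            val_ds = pool_datasets(eval_sets)
        else:
            idx = rng.permutation(len(pooled))
            n_val = max(1, int(round(cfg.val_fraction * len(pooled))))
            val_ds = pooled.subset(idx[:n_val])
            train_ds = pooled.subset(idx[n_val:])
        states: dict[int, TrainState] = {}
        for k in self.ks:
            states[k] = self._fine_tune_one(k, train_ds, val_ds, epochs,
                                            rng.integers(2 ** 31))
        self.history.extend(states.values())
        return states

    def _fine_tune_one(self, k: int, train_ds: LabeledDataset,
                       val_ds: LabeledDataset, epochs: int,
                       seed: int) -> TrainState:
        cfg = self.train_config
        encoder = self.encoders[k]
        head = _FineTuneHead(self.encoder_configs[k].d_m,
                             np.random.default_rng(seed))
        max_len = self.sequence_length - k + 3
        ids, masks = encode_batch_ids(train_ds.sequences, k,
                                      self.vocabs[k], max_len)
        labels = train_ds.labels
        val_ids, val_masks = encode_batch_ids(val_ds.sequences, k,
                                              self.vocabs[k], max_len)
        val_labels = val_ds.labels
        opt = AdamW(encoder.parameters() + head.parameters(),
                    lr=cfg.fine_tune_lr,
                    weight_decay=cfg.fine_tune_weight_decay)
        rng = np.random.default_rng(seed)
        state = TrainState(stage=f"fine_tune_k{k}")
        best_state = None
        for epoch in range(epochs):
            encoder.train()
            head.train()
            order = rng.permutation(len(labels))
            losses = []
            for start in range(0, len(order), cfg.fine_tune_batch_size):
                batch = order[start:start + cfg.fine_tune_batch_size]
                logits = head(encoder(ids[batch], masks[batch]))
                loss = cross_entropy(logits, labels[batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            encoder.eval()
            head.eval()
            with no_grad():
                logits = head(encoder(val_ids, val_masks)).data
            acc = float((logits.argmax(axis=1) == val_labels).mean())
            state.loss_trace.append(float(np.mean(losses)))
            state.metric_trace.append({"ACC": acc})
            if state.best_metric is None or acc > state.best_metric:
                state.best_metric = acc
                state.best_epoch = epoch
                best_state = copy.deepcopy(encoder.state_dict())
        if best_state is not None:
            encoder.load_state_dict(best_state)
        return state

    # -- stage 1 ---------------------------------------------------------
    def train_stage1(self, train_sequences: list[str] | None = None,
                     view_embeddings: dict[int, np.ndarray] | None = None,
                     epochs: int | None = None) -> TrainState:
        """Train the decoding part on frozen, cached view embeddings.

        Only {W^v, g^v, ẑ_n} are updated; encoders and classifier are
        untouched. The recorded trace holds the full decoding objective
        (L_r + β Σ||W^v||_{2,1}) at initialisation and after every epoch.
        """
        cfg = self.train_config
        epochs = cfg.stage1_epochs if epochs is None else epochs
        if view_embeddings is None:
            if train_sequences is None:
                raise ValueError("provide sequences or cached view embeddings")
            view_embeddings, _ = self.view_embeddings(train_sequences)
        x_views = [np.asarray(view_embeddings[k], dtype=np.float32)
                   for k in self.ks]
        n = x_views[0].shape[0]
        self.fusion.init_auxiliary(n)
        self._encoded_cache = {k: x for k, x in zip(self.ks, x_views)}
        opt = SGD(self.fusion.decoding_parameters(), lr=cfg.stage1_lr,
                  weight_decay=cfg.stage1_weight_decay)
        rng = np.random.default_rng(cfg.seed + 401)
        state = TrainState(stage="stage1")
        all_idx = np.arange(n)
        self.fusion.train()
        state.loss_trace.append(
            self.fusion.decoding_objective(x_views, all_idx))
        beta = self.fusion.config.beta
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.stage1_batch_size):
                batch = order[start:start + cfg.stage1_batch_size]
                loss = self.fusion.reconstruction_loss(
                    [x[batch] for x in x_views], batch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                if beta > 0:
                    for W in self.fusion.relation_matrices:
                        prox_l21_(W, cfg.stage1_lr * beta)
            state.loss_trace.append(
                self.fusion.decoding_objective(x_views, all_idx))
        self.history.append(state)
        return state

    # -- stage 2 ---------------------------------------------------------
    def train_stage2(self, train_sequences: list[str],
                     train_labels: np.ndarray,
                     epochs: int | None = None) -> TrainState:
        """End-to-end training of encoders, fusion encoders and classifier.

        Requires stage 1 (the ẑ table indexed in the order of
        ``train_sequences``). δ is annealed by epoch, so the alignment loss
        stops contributing from epoch 10 on.
        """
        if self.fusion.z_hat is None:
            raise ValueError("run train_stage1 before train_stage2")
        cfg = self.train_config
        epochs = cfg.stage2_epochs if epochs is None else epochs
        labels = np.asarray(train_labels, dtype=np.int64)
        encoded = self.encode_inputs(train_sequences)
        n = len(labels)
        encoder_params = []
        for k in self.ks:
            encoder_params.extend(self.encoders[k].parameters())
        head_params = (self.fusion.encoding_parameters()
                       + self.classifier.parameters())
        opt = AdamW([
            {"params": encoder_params, "lr": cfg.lr_encoder,
             "weight_decay": cfg.weight_decay_encoder},
            {"params": head_params, "lr": cfg.lr_fusion_head,
             "weight_decay": cfg.weight_decay_fusion_head},
        ], lr=cfg.lr_encoder)
        rng = np.random.default_rng(cfg.seed + 501)
        state = TrainState(stage="stage2")
        for t in range(epochs):
            for module in (self.fusion, self.classifier,
                           *self.encoders.values()):
                module.train()
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.stage2_batch_size):
                batch = order[start:start + cfg.stage2_batch_size]
                x_views = []
                for k in self.ks:
                    ids, masks = encoded[k]
                    x_views.append(self.encoders[k](ids[batch], masks[batch]))
                z = self.fusion.fuse(x_views)
                logits = self.classifier(z)
                loss = self.fusion.total_objective(
                    logits, labels[batch], x_views, batch, t, z=z)
                opt.zero_grad()
                self.fusion.z_hat.grad = None  # frozen in stage 2
                loss.backward()
                opt.step()
                losses.append(loss.item())
            state.loss_trace.append(float(np.mean(losses)))
        self.history.append(state)
        return state

    # -- orchestration ---------------------------------------------------
    def fit(self, train: LabeledDataset,
            fine_tune_sets: list[LabeledDataset] | None = None,
            eval_sets: list[LabeledDataset] | None = None,
            fine_tune_epochs: int | None = None,
            stage1_epochs: int | None = None,
            stage2_epochs: int | None = None) -> "MethylationPredictor":
        """Full protocol: optional fine-tuning, then stage 1, then stage 2."""
        if fine_tune_sets:
            self.fine_tune_multispecies(fine_tune_sets, eval_sets,
                                        epochs=fine_tune_epochs)
        self.train_stage1(train_sequences=train.sequences,
                          epochs=stage1_epochs)
        self.train_stage2(train.sequences, train.labels,
                          epochs=stage2_epochs)
        return self

    # -- inference -------------------------------------------------------
    def predict_proba(self, sequences: list[str]) -> np.ndarray:
        """Probability of methylation per sequence (deterministic, eval mode)."""
        views, _ = self.view_embeddings(sequences)
        self.fusion.eval()
        self.classifier.eval()
        with no_grad():
            z = self.fusion.fuse([views[k] for k in self.ks])
            logits = self.classifier(z)
            probs = logits.softmax(axis=-1).data
        return probs[:, 1]

    def predict(self, sequences: list[str],
                threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(sequences) >= threshold).astype(np.int64)

    def evaluate(self, dataset: LabeledDataset) -> MetricsReport:
        scores = self.predict_proba(dataset.sequences)
        return evaluate_predictions(dataset.labels, scores)

    def cross_species_evaluate(self, test_split: LabeledDataset) -> MetricsReport:
        """Metrics of this (species-A-trained) model on species B's test set."""
        return self.evaluate(test_split)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        state: dict[str, np.ndarray] = {}
        for k in self.ks:
            for name, arr in self.encoders[k].state_dict().items():
                state[f"encoder_k{k}.{name}"] = arr
        for name, arr in self.fusion.state_dict().items():
            state[f"fusion.{name}"] = arr
        for name, arr in self.classifier.state_dict().items():
            state[f"classifier.{name}"] = arr
        if self.fusion.z_hat is not None:
            state["fusion.z_hat"] = self.fusion.z_hat.data
        np.savez(directory / "weights.npz", **state)
        meta = {
            "ks": list(self.ks),
            "sequence_length": self.sequence_length,
            "encoder_config": {k: self.encoder_configs[k].to_dict()
                               for k in self.ks},
            "fusion_config": self.fusion.config.to_dict(),
            "train_config": self.train_config.to_dict(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "MethylationPredictor":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        any_enc = next(iter(meta["encoder_config"].values()))
        enc_kwargs = {key: any_enc[key] for key in
                      ("num_blocks", "d_m", "num_heads", "d_k", "ffn_dim",
                       "max_positions", "dropout")}
        fusion_cfg = FusionConfig(**meta["fusion_config"])
        model = cls(ks=tuple(meta["ks"]),
                    sequence_length=meta["sequence_length"],
                    encoder_config=enc_kwargs,
                    fusion_config=fusion_cfg,
                    train_config=TrainConfig(**meta["train_config"]))
        with np.load(directory / "weights.npz") as archive:
            state = {key: archive[key] for key in archive.files}
        if "fusion.z_hat" in state:
            model.fusion.init_auxiliary(state["fusion.z_hat"].shape[0])
        for k in model.ks:
            prefix = f"encoder_k{k}."
            model.encoders[k].load_state_dict(
                {name[len(prefix):]: arr for name, arr in state.items()
                 if name.startswith(prefix)})
        model.fusion.load_state_dict(
            {name[7:]: arr for name, arr in state.items()
             if name.startswith("fusion.")})
        model.classifier.load_state_dict(
            {name[11:]: arr for name, arr in state.items()
             if name.startswith("classifier.")})
        return model


def cross_species_matrix(species: list[tuple[LabeledDataset, LabeledDataset]],
                         model_factory) -> np.ndarray:
    """ACC of a model trained on species i evaluated on species j's test set.

    ``species`` is a list of (train_split, test_split) pairs;
    ``model_factory(i, train_split)`` must return a fitted predictor.
    Returns the n x n matrix of accuracies (diagonal = within-species).
    """
    n = len(species)
    accs = np.zeros((n, n))
    for i, (train_i, _) in enumerate(species):
        model = model_factory(i, train_i)
        for j, (_, test_j) in enumerate(species):
            accs[i, j] = model.cross_species_evaluate(test_j).acc
    return accs
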