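# Methods

## Task and model

The classification target is the methylation status of the central base of
a fixed-length DNA window (41 bp default; adenine at the centre for 6mA,
cytosine for 4mC/5hmC — in positives *and* negatives, so base identity
carries no label information). The model views each window through four
k-mer tokenizations (k = 3..6), encodes each view with its own BERT-style
transformer, fuses the per-view embeddings into one comprehensive
representation, and classifies with a two-layer head.

### Tokenization

Sliding window of width k, stride 1: L − k + 1 tokens. The vocabulary for
one k holds the 4^k k-mers in lexicographic order (A < C < G < T) after
five special tokens at fixed ids 0–4 (`[CLS] [PAD] [UNK] [SEP] [MASK]`).
The ordering is a package choice — any fixed order works, but determinism
is required for reproducible checkpoints. Windows containing N map to
`[UNK]` rather than being dropped, preserving the token-count contract;
characters outside ACGTN are an error (fail fast on malformed input).
Sequences are framed `[CLS] … [SEP]` and right-padded.

### Encoder

Token + learned absolute position embeddings (standard BERT convention),
`num_blocks` transformer blocks (multi-head scaled dot-product attention
and a ReLU feed-forward sublayer, each wrapped in residual + layer
normalisation), and a pooler (dense + Tanh on the `[CLS]` state). Padded
keys receive −10⁹ before the softmax, so they get zero attention weight
and padded token ids cannot influence the pooled embedding. Geometry is
configurable; the published-scale geometry (12 blocks, d_m = 768,
12 heads) is constructible, while the desk-scale default used throughout
the tests and experiments is 2 blocks, d_m = 64, 2 heads, feed-forward
width 4·d_m, dropout 0.1. All computation is float32; the attention
softmax is max-shifted for stability.

### Fusion

Stage-1 ("decoding part") trainables: relation matrices W^v ∈ R^{d×h_dec},
two-layer ReLU decoders g^v, and one free auxiliary vector ẑ_n ∈ R^d per
training sample (initialised N(0, 0.1); test samples never have one — the
encoding part exists precisely to handle out-of-sample inputs). Objective:
L_r + β Σ_v ‖W^v‖₂,₁ with L_r the sample-mean, view-sum of squared
reconstruction errors (no 1/V factor).

Stage-2 ("encoding part") trainables: two-layer encoders f^v with batch
normalisation in every layer (batch stats while training, running stats at
inference, momentum 0.1), scalars a (init 1) and b (init 0), and the
classifier. The fused representation is the arithmetic mean of the V
encoder outputs. The BN-weight guidance term ‖w^v − σ(a w̄^v + b)‖², with
w̄^v the column-mean of |W^v| (a length-d vector, dividing by h_dec), is
summed over all V views inside L_a — the per-view definition admits no
other consistent reading. The stage-2 objective multiplies the *batch-mean*
cross-entropy by λ₁ and adds δ(t)·L_a and the L1 term once per batch
(L_a is already sample-averaged; re-averaging would double-count 1/N).
The L1 sparsity term applies to the raw BN weight vectors w^v, not the
σ-guided targets.

## Training protocol

1. **Fine-tuning** (optional but part of the full protocol): each view
   encoder trains with a temporary dense head on the (possibly
   multi-species pooled) training split; one checkpoint per epoch; the
   checkpoint with the highest evaluation ACC is kept. Evaluation uses a
   10 % held-out fraction carved from the training split by default. A
   `paper_protocol` flag instead selects on the pooled test split — an
   optimistic protocol (selection leak) provided for comparability, not
   endorsed. AdamW, lr 1e-4, weight decay 1e-3 (a standard BERT
   fine-tuning setting; chosen here, with 20 epochs as the default).
2. **Stage 1**: SGD, lr 5e-5, weight decay 3e-3, on cached (frozen-encoder)
   view embeddings; default 50 epochs, batch 128. The smooth part of the
   objective takes a gradient step; the L2,1 penalty is applied through its
   proximal operator (row-norm shrinkage by lr·β, clamping at zero).
   Proximal gradient is the standard optimiser for this penalty: a
   subgradient step oscillates around zero and never produces the exactly
   (or near-) zero rows the structured-sparsity interpretation relies on.
   Encoders and classifier are untouched (verified by checksum in tests).
3. **Stage 2**: AdamW with two parameter groups — pre-trained encoders at
   (lr 3e-5, wd 1e-3), freshly initialised fusion encoders + classifier +
   a, b at (lr 5e-5, wd 3e-3); the larger step for fresh parameters is
   standard practice. δ anneals to zero by epoch 10; ẑ is frozen. Default
   10 epochs, batch 32.

Default fusion hyperparameters: β = 0.1, γ = 0.1, λ₁ = 1, λ₂ = 1e-4,
d = 128, h_dec = 64 (desk-scale experiments use d = 64, h_dec = 32 to
match the d_m = 64 encoders). All hyperparameters and seeds are logged to
the run manifest; every random draw flows through explicitly seeded
generators (no global RNG state), making end-to-end runs reproducible.

## Synthetic benchmark

The generator emulates the structure of the 41-bp methylation benchmarks:
balanced classes, fixed length, forced central target base. Positives
carry an IUPAC consensus motif (default SAGGY = [G/C]AGG[C/T], the
conserved 6mA pattern) planted at a fixed anchor (default positions
20–24, overlapping the central adenine); IUPAC letters resolve uniformly
over their allowed bases. Negatives are uniform-background sequences with
any chance match of the consensus at the anchor resampled away; matches
elsewhere are left at their background rate. Species families for
transfer experiments share the motif (conserved patterns) or draw
pairwise-distinct motifs at distinct anchors (divergent patterns).

What this does *not* emulate: positional composition gradients of real
genomes, CpG-island context, near-duplicate sequences, label noise, or
class imbalance. Passing tests therefore demonstrate that the machinery
learns and localises position-specific sequence patterns under controlled
conditions — not benchmark-level accuracy on real species data, which
additionally requires genome-scale pre-trained encoders.

## Experiment sizes

The standard in-package experiment uses 2000 train / 500 test sequences,
the 2-block d_m = 64 encoder, 6 fine-tuning epochs, 50 stage-1 and 10
stage-2 epochs (≈ 2–3 minutes on one CPU); it reaches test ACC ≥ 0.99 and
the trained attention's width-5 top window overlaps the planted region in
≥ 97 % of positive test sequences (vs ≈ 10–25 % untrained). Cross-species
runs use 500 + 500 sequences per species with 8 fine-tuning and 10
stage-2 epochs. The sparsity sweep runs stage 1 to convergence
(400 epochs, lr 1e-3) because row sparsity is an asymptotic property of
the regularised optimum.

## Numerical and design choices

* Attention saliency is "attention received" (column means over real-token
  query rows, specials excluded before any averaging) — the common saliency
  convention; a `cls_row` mode is available. Per-sequence normalisation is
  applied before averaging profiles across views.
* Position projection: a nucleotide position inherits the mean score of
  the k-mer tokens covering it; ties in window extraction break leftmost.
* MCC is reported as 0 and flagged when a denominator factor vanishes.
* ROC/PR sweep thresholds at unique scores with ties grouped, so the
  trapezoidal AUC equals the Mann–Whitney pair probability with ½ tie
  credit, and AP is the step-wise precision-weighted recall sum.
* Checkpoints are `.npz` key→tensor archives with the configuration as
  JSON beside them; shape mismatches report the offending parameter name.

## Known limitations

* The alignment loss anchors only the view-*mean* z_n to ẑ_n; nothing in
  the objective pulls the individual z_n^v toward each other, and once δ
  anneals away the cross-entropy term dominates. Empirically the
  cross-view spread of z_n^v is not consistently smaller than that of the
  raw embeddings; what holds (and is tested) is that with the
  classification term disabled the δ-normalised alignment loss decreases
  epoch over epoch — the guidance mechanism works, but "the views become
  mutually closer" is not a guaranteed consequence of it.
* Batch-norm train/eval statistics differ, so loss values monitored during
  training are not directly comparable to eval-mode recomputation.
* The autodiff core implements exactly the operations this model needs; it
  is not a general-purpose framework (no higher-order gradients, no GPU).
* Fine-tuning every view encoder dominates runtime; paper-scale geometry
  is constructible but impractical without hardware acceleration.
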