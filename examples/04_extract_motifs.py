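"""Recover the planted motif from the trained model's attention.

Token saliency = mean attention received across the last transformer
block's heads, projected onto nucleotide positions and averaged over the
four k-mer views. The top-scoring width-5 windows of positive sequences
are stacked into a position frequency matrix and written in MEME minimal
format (comparable against STREME/TOMTOM output).
"""

from pathlib import Path

import numpy as np

from methylfusion import (FusionConfig, GeneratorConfig, MethylationPredictor,
                          TrainConfig, generate_dataset, train_test_split)
from methylfusion.motifs import (aggregate_pfm, averaged_position_profile,
                                 extract_top_window,
                                 position_profile_from_attention,
                                 write_meme_motif)

dataset = generate_dataset(GeneratorConfig(n_pos=300, n_neg=300, seed=11))
train, test = train_test_split(dataset, 0.8, seed=11)
model = MethylationPredictor(
    encoder_config=dict(num_blocks=2, d_m=64, num_heads=2),
    fusion_config=FusionConfig(d=64, h_dec=32, embed_dim=64),
    train_config=TrainConfig(seed=7))
model.fit(train, fine_tune_sets=[train], fine_tune_epochs=6,
          stage2_epochs=10)

positives = [r.sequence for r in test if r.label == 1]
_, attention = model.view_embeddings(positives, return_attention=True)
anchors = []
for i in range(len(positives)):
    profiles = [position_profile_from_attention(
        attention[k][0][i], attention[k][1][i], k, 41) for k in model.ks]
    anchors.append(extract_top_window(averaged_position_profile(profiles), 5))

hits = sum(s <= 24 and e >= 20 for s, e in anchors)
pfm = aggregate_pfm(positives, anchors, width=5)
out = Path("example_output")
out.mkdir(exist_ok=True)
write_meme_motif(pfm, out / "motif.meme", name="attention_motif")

print(f"top attention window overlaps the planted 20-24 region in "
      f"{hits}/{len(positives)} positive test sequences")
print(f"consensus of the extracted windows: {pfm.consensus()} "
      f"(planted: [G/C]AGG[C/T])")
print("frequencies (rows A,C,G,T):")
print(np.round(pfm.frequencies, 2))
print(f"MEME motif written to {out / 'motif.meme'}")
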