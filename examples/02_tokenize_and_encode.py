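"""Tokenize a DNA sequence with several k-mer sizes and encode it.

A length-L sequence yields L-k+1 overlapping k-mers; each k has its own
4^k + 5 token vocabulary ([CLS]/[PAD]/[UNK]/[SEP]/[MASK] + all k-mers).
The encoder pools the [CLS] state into one embedding per sequence.
"""

import numpy as np

from methylfusion import EncoderConfig, TransformerEncoder, build_vocabulary, tokenize
from methylfusion.encoder import encode_batch
from methylfusion.tokenization import encode_batch_ids

seq = "ATTAA"
for k in (3, 4):
    ts = tokenize(seq, k)
    print(f"{seq} with k={k}: {len(ts.tokens)} tokens -> {', '.join(ts.tokens)}")

for k in (3, 4, 5, 6):
    print(f"k={k}: vocabulary size 4^{k}+5 = {len(build_vocabulary(k))}")

# encode a batch of 41-bp sequences with the desk-scale encoder
rng = np.random.default_rng(0)
seqs = ["".join(rng.choice(list("ACGT"), 41)) for _ in range(4)]
vocab = build_vocabulary(6)
ids, masks = encode_batch_ids(seqs, 6, vocab, max_length=38)
encoder = TransformerEncoder(EncoderConfig(vocab_size=len(vocab), num_blocks=2,
                                           d_m=64, num_heads=2,
                                           max_positions=43, seed=0))
pooled, attention = encode_batch(encoder, ids, masks, return_attention=True)
print(f"pooled embeddings: {pooled.shape} (one length-64 vector per sequence, "
      f"all in (-1, 1) from the Tanh pooler)")
print(f"last-block attention: {attention.shape} "
      f"(batch x heads x tokens x tokens, rows sum to 1)")
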