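"""Generate a synthetic planted-motif methylation benchmark.

Builds 41-bp sequences with a central adenine (the 6mA target base) and the
conserved consensus [G/C]AGG[C/T] planted at positions 20-24 in positives,
then writes FASTA and TSV files plus a run manifest.
"""

from pathlib import Path

from methylfusion import GeneratorConfig, generate_dataset, train_test_split
from methylfusion.io import write_fasta, write_labeled_table, write_manifest

cfg = GeneratorConfig(n_pos=200, n_neg=200, seed=7)
dataset = generate_dataset(cfg)
train, test = train_test_split(dataset, 0.8, seed=7)

out = Path("example_output/dataset")
out.mkdir(parents=True, exist_ok=True)
write_fasta(train, out / "train.fasta")
write_fasta(test, out / "test.fasta")
write_labeled_table(train, out / "train.tsv")
write_labeled_table(test, out / "test.tsv")
write_manifest(out, {"generator": cfg.to_dict()}, seed=7)

pos = train.records[0]
neg = next(r for r in train if r.label == 0)
print(f"{len(train)} train / {len(test)} test records, all {train.length} bp")
print(f"positive  {pos.sequence}  (motif at 20-24: {pos.sequence[19:24]})")
print(f"negative  {neg.sequence}  (window 20-24:  {neg.sequence[19:24]})")
print("Positives carry the SAGGY consensus at the anchor; negatives never do.")
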