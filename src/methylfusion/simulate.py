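"""Synthetic planted-motif benchmark generator.

Emulates the structure of the 41-bp methylation benchmark: every record is
a fixed-length window whose central base is the methylation target (A for
6mA, C for 4mC/5hmC) in positives *and* negatives — the task is the
methylation status of that base, not its identity. Positives carry an
IUPAC consensus motif planted at a fixed anchor (default [G/C]AGG[C/T],
written SAGGY, at positions 20-24, the conserved 6mA pattern); negatives
are background sequences with any chance occurrence of the consensus at
the anchor resampled away. All randomness flows through one seeded
generator, so datasets are byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneratorConfig", "SequenceRecord", "LabeledDataset",
           "generate_dataset", "train_test_split", "make_species_family",
           "IUPAC"]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CENTRAL_BASE = {"4mC": "C", "5hmC": "C", "6mA": "A"}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 1000
    n_neg: int = 1000
    length: int = 41
    methyl_type: str = "6mA"
    motif: str = "SAGGY"
    motif_start: int = 20           # 1-based anchor of the planted motif
    plant_prob: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        if self.methyl_type not in _CENTRAL_BASE:
            raise ValueError(f"methyl_type must be one of "
                             f"{sorted(_CENTRAL_BASE)}, got {self.methyl_type!r}")
        if self.length % 2 == 0:
            raise ValueError("length must be odd so a central base exists")
        if not set(self.motif) <= set(IUPAC):
            raise ValueError(f"motif contains non-IUPAC letters: {self.motif}")
        if self.motif_start < 1 or \
                self.motif_start + len(self.motif) - 1 > self.length:
            raise ValueError("motif window must lie inside the sequence")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must be in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector over ACGT")
        centre = self.central_position
        offset = centre - self.motif_start
        if 0 <= offset < len(self.motif):
            allowed = IUPAC[self.motif[offset]]
            if self.central_base not in allowed:
                raise ValueError(
                    f"motif letter {self.motif[offset]!r} at the central "
                    f"position excludes the {self.methyl_type} target base "
                    f"{self.central_base!r}")

    @property
    def central_position(self) -> int:
        """1-based position of the methylation target base."""
        return (self.length + 1) // 2

    @property
    def central_base(self) -> str:
        return _CENTRAL_BASE[self.methyl_type]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    label: int
    split: str | None = None


@dataclass(frozen=True)
class LabeledDataset:
    records: tuple[SequenceRecord, ...]
    name: str = "synthetic"
    config: GeneratorConfig | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def subset(self, indices, split: str | None = None) -> "LabeledDataset":
        recs = [self.records[i] for i in np.atleast_1d(np.asarray(indices))]
        if split is not None:
            recs = [dataclasses.replace(r, split=split) for r in recs]
        return LabeledDataset(records=tuple(recs), name=self.name,
                              config=self.config)


def _matches_consensus(window: str, motif: str) -> bool:
    return all(base in IUPAC[letter] for base, letter in zip(window, motif))


def _sample_background(rng: np.random.Generator, length: int,
                       background) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(background))


def _resolve_motif(rng: np.random.Generator, motif: str) -> str:
    """Resolve IUPAC letters uniformly among their allowed bases."""
    return "".join(IUPAC[letter][rng.integers(len(IUPAC[letter]))]
                   for letter in motif)


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Positives first (label 1), then negatives (label 0)."""
    rng = np.random.default_rng(config.seed)
    centre_idx = config.central_position - 1
    anchor = config.motif_start - 1
    width = len(config.motif)
    records: list[SequenceRecord] = []

    for i in range(config.n_pos):
        codes = _sample_background(rng, config.length, config.background)
        seq = _BASES[codes]
        if rng.random() < config.plant_prob:
            seq[anchor:anchor + width] = list(
                _resolve_motif(rng, config.motif))
        seq[centre_idx] = config.central_base
        records.append(SequenceRecord(id=f"pos_{i}",
                                      sequence="".join(seq), label=1))

    for i in range(config.n_neg):
        while True:
            codes = _sample_background(rng, config.length, config.background)
            seq = _BASES[codes]
            seq[centre_idx] = config.central_base
            window = "".join(seq[anchor:anchor + width])
            if not _matches_consensus(window, config.motif):
                break
        records.append(SequenceRecord(id=f"neg_{i}",
                                      sequence="".join(seq), label=0))

    return LabeledDataset(records=tuple(records), config=config)


def train_test_split(dataset: LabeledDataset, fraction: float,
                     seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified-by-label disjoint split; ``fraction`` goes to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    mk = lambda idxs, tag: LabeledDataset(
        records=tuple(dataclasses.replace(dataset.records[i], split=tag)
                      for i in idxs),
        name=dataset.name, config=dataset.config)
    return mk(train_idx, "train"), mk(test_idx, "test")


# motifs offered to disjoint synthetic "species"; anchors keep each window
# clear of conflicts with the forced central base
_SPECIES_MOTIFS: tuple[tuple[str, int], ...] = (
    ("SAGGY", 20), ("GCGSW", 8), ("AAWTT", 30), ("CCGAY", 12),
    ("TGCWG", 33), ("RTTAC", 3),
)


def make_species_family(shared_motif: bool, n_species: int,
                        config: GeneratorConfig) -> list[LabeledDataset]:
    """Synthetic species for cross-species transfer experiments.

    Shared: every species plants the same motif (transfer should succeed).
    Disjoint: pairwise-distinct motifs at distinct anchors (transfer should
    degrade).
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if not shared_motif and n_species > len(_SPECIES_MOTIFS):
        raise ValueError(
            f"only {len(_SPECIES_MOTIFS)} distinct motifs available")
    datasets = []
    for s in range(n_species):
        if shared_motif:
            motif, start = config.motif, config.motif_start
        else:
            motif, start = _SPECIES_MOTIFS[s]
        cfg = dataclasses.replace(config, motif=motif, motif_start=start,
                                  seed=config.seed + 1000 * (s + 1))
        ds = generate_dataset(cfg)
        datasets.append(LabeledDataset(records=ds.records,
                                       name=f"species_{s}", config=cfg))
    return datasets
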