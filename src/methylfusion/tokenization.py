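"""k-mer tokenization of DNA sequences.

A length-L sequence yields L - k + 1 overlapping k-mers (stride 1). For each
k the vocabulary holds all 4^k k-mers over {A, C, G, T} plus five special
tokens ([CLS], [PAD], [UNK], [SEP], [MASK]), i.e. 4^k + 5 entries. Windows
containing an ambiguous base (N) map to [UNK] so the length contract is
preserved. Token ids are deterministic: specials occupy ids 0-4, k-mers
follow in lexicographic order (A < C < G < T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

SPECIAL_TOKENS: tuple[str, ...] = ("[CLS]", "[PAD]", "[UNK]", "[SEP]", "[MASK]")
CLS, PAD, UNK, SEP, MASK = SPECIAL_TOKENS
_BASES = "ACGT"
DEFAULT_KS: tuple[int, ...] = (3, 4, 5, 6)


@dataclass(frozen=True)
class Vocabulary:
    """Token inventory for one k: 4^k k-mers plus the five special tokens."""

    k: int
    token_to_id: dict[str, int] = field(repr=False)
    id_to_token: tuple[str, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, self.token_to_id[UNK])

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    def decode(self, ids) -> list[str]:
        return [self.id_to_token[i] for i in ids]

    def save(self, path: str | Path) -> None:
        """Write one token per line, in id order (DNABERT-style layout)."""
        Path(path).write_text("\n".join(self.id_to_token) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = Path(path).read_text().split()
        k = len(tokens[-1])
        vocab = build_vocabulary(k)
        if list(vocab.id_to_token) != tokens:
            raise ValueError(f"{path} is not a valid k={k} vocabulary file")
        return vocab


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized sequence: L - k + 1 k-mer tokens of one source sequence."""

    k: int
    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    source_length: int


def build_vocabulary(k: int) -> Vocabulary:
    """All 4^k k-mers in lexicographic order preceded by the five specials."""
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= 8:
        raise ValueError(f"k must be an integer in [1, 8], got {k!r}")
    id_to_token = SPECIAL_TOKENS + tuple(
        "".join(p) for p in product(_BASES, repeat=k))
    token_to_id = {tok: i for i, tok in enumerate(id_to_token)}
    return Vocabulary(k=int(k), token_to_id=token_to_id, id_to_token=id_to_token)


def _normalize(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(
            f"sequence contains characters outside ACGTN: {sorted(bad)}")
    return seq


def tokenize(sequence: str, k: int, vocab: Vocabulary | None = None) -> TokenSequence:
    """Slide a width-k window (stride 1) over the sequence.

    Windows containing N become [UNK]; lowercase input is upper-cased;
    any other character raises.
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    seq = _normalize(sequence)
    if len(seq) < k:
        raise ValueError(
            f"sequence length {len(seq)} is shorter than k={k}")
    if vocab is None:
        vocab = build_vocabulary(k)
    elif vocab.k != k:
        raise ValueError(f"vocabulary k={vocab.k} does not match k={k}")
    tokens = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        tokens.append(UNK if "N" in window else window)
    ids = tuple(vocab[t] for t in tokens)
    return TokenSequence(k=k, tokens=tuple(tokens), ids=ids,
                         source_length=len(seq))


def encode_ids(tokens: TokenSequence, vocab: Vocabulary,
               max_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Frame as [CLS] tokens [SEP], right-pad with [PAD] to ``max_length``.

    Returns (ids, attention_mask) as int64/float32 arrays of length
    ``max_length``; the mask is 1 on real positions and 0 on padding.
    """
    if tokens.k != vocab.k:
        raise ValueError(f"token k={tokens.k} != vocabulary k={vocab.k}")
    framed = [vocab.cls_id, *(vocab[t] for t in tokens.tokens), vocab.sep_id]
    if len(framed) > max_length:
        raise ValueError(
            f"framed length {len(framed)} exceeds max_length {max_length}")
    n_pad = max_length - len(framed)
    ids = np.array(framed + [vocab.pad_id] * n_pad, dtype=np.int64)
    mask = np.zeros(max_length, dtype=np.float32)
    mask[:len(framed)] = 1.0
    return ids, mask


def encode_batch_ids(sequences: list[str], k: int, vocab: Vocabulary,
                     max_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised framing of many sequences into (N, max_length) id/mask arrays."""
    ids = np.empty((len(sequences), max_length), dtype=np.int64)
    masks = np.empty((len(sequences), max_length), dtype=np.float32)
    for i, seq in enumerate(sequences):
        ids[i], masks[i] = encode_ids(tokenize(seq, k, vocab), vocab, max_length)
    return ids, masks
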