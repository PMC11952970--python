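"""Attention-based motif extraction.

A trained encoder's last transformer block tells us where the model looks:
averaging attention weights over its heads gives each k-mer token a
saliency score ("attention received" — the mean weight assigned to the
token across all real-token query rows). Token scores from views with
different k are projected onto nucleotide positions (a position inherits
the mean score of the tokens covering it), making profiles comparable
across k and across views. High-attention windows anchored on these
profiles are stacked into a position frequency matrix and can be written
in MEME minimal motif format for downstream comparison (e.g. TOMTOM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AttentionProfile", "MotifMatrix", "token_attention_profile",
           "project_to_positions", "extract_top_window", "aggregate_pfm",
           "write_meme_motif"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class AttentionProfile:
    k: int
    token_scores: np.ndarray = field(repr=False)
    position_scores: np.ndarray = field(repr=False)

    @property
    def source_length(self) -> int:
        return self.position_scores.shape[0]


@dataclass(frozen=True)
class MotifMatrix:
    """Base counts/frequencies over aligned high-attention windows."""

    width: int
    counts: np.ndarray = field(repr=False)        # (4, width) ints
    frequencies: np.ndarray = field(repr=False)   # (4, width), columns sum to 1
    n_sequences: int
    anchor: tuple[int, int] | None = None         # 1-based inclusive range

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.frequencies.argmax(axis=0))


def token_attention_profile(attention: np.ndarray, mask: np.ndarray,
                            mode: str = "received") -> np.ndarray:
    """Per-token saliency from a last-block attention tensor (heads, L, L).

    ``received``: mean over heads of the mean attention received by each
    token over all real-token query rows. ``cls_row``: mean over heads of
    the [CLS] query row. Special positions ([CLS] at 0, [SEP] at the end of
    the real span, [PAD] beyond) are excluded from the result, which has
    one entry per real k-mer token.
    """
    attention = np.asarray(attention)
    if attention.ndim != 3:
        raise ValueError("expected (heads, L, L) attention for one sequence")
    mask = np.asarray(mask)
    real = int(mask.sum())            # [CLS] + tokens + [SEP]
    token_slice = slice(1, real - 1)  # strip framing
    if mode == "received":
        sub = attention[:, token_slice, token_slice]
        scores = sub.mean(axis=(0, 1))
    elif mode == "cls_row":
        scores = attention[:, 0, token_slice].mean(axis=0)
    else:
        raise ValueError(f"unknown attention mode: {mode!r}")
    return scores


def project_to_positions(token_scores: np.ndarray, k: int, length: int
                         ) -> np.ndarray:
    """Score of position p = mean score of the k-mer tokens covering p.

    A token starting at s (1-based) covers positions s..s+k-1, so position p
    is covered by tokens starting in [max(1, p-k+1), min(p, length-k+1)].
    """
    token_scores = np.asarray(token_scores, dtype=float)
    n_tokens = length - k + 1
    if token_scores.shape[0] != n_tokens:
        raise ValueError(
            f"expected {n_tokens} token scores for length {length}, k={k}; "
            f"got {token_scores.shape[0]}")
    out = np.empty(length, dtype=float)
    for p in range(1, length + 1):
        lo = max(1, p - k + 1)
        hi = min(p, n_tokens)
        out[p - 1] = token_scores[lo - 1:hi].mean()
    return out


def extract_top_window(position_scores: np.ndarray, width: int
                       ) -> tuple[int, int]:
    """Contiguous window of maximal summed score; leftmost on ties.

    Returns the 1-based inclusive (start, end) range.
    """
    scores = np.asarray(position_scores, dtype=float)
    if width > scores.shape[0]:
        raise ValueError("window width exceeds profile length")
    sums = np.convolve(scores, np.ones(width), mode="valid")
    start = int(np.argmax(sums))      # argmax returns the first maximum
    return start + 1, start + width


def aggregate_pfm(sequences: list[str], anchors: list[tuple[int, int]],
                  width: int | None = None) -> MotifMatrix:
    """Stack anchored windows into a position frequency matrix."""
    if len(sequences) != len(anchors):
        raise ValueError("one anchor per sequence required")
    if width is None:
        width = anchors[0][1] - anchors[0][0] + 1
    counts = np.zeros((4, width), dtype=np.int64)
    for seq, (start, end) in zip(sequences, anchors):
        if end - start + 1 != width:
            raise ValueError(f"anchor ({start}, {end}) has width "
                             f"{end - start + 1}, expected {width}")
        if start < 1 or end > len(seq):
            raise ValueError(
                f"anchor ({start}, {end}) outside sequence of length {len(seq)}")
        window = seq[start - 1:end].upper()
        for j, base in enumerate(window):
            counts[_BASE_INDEX[base], j] += 1
    n = len(sequences)
    return MotifMatrix(width=width, counts=counts,
                       frequencies=counts / float(n), n_sequences=n)


def write_meme_motif(matrix: MotifMatrix, path: str | Path,
                     name: str = "motif_1") -> None:
    """MEME minimal motif format (version 4, ACGT alphabet)."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {matrix.width} "
        f"nsites= {matrix.n_sequences} E= 0",
    ]
    for col in matrix.frequencies.T:
        lines.append(" ".join(f"{v:.6f}" for v in col))
    lines.append("")
    try:
        Path(path).write_text("\n".join(lines))
    except OSError as exc:
        raise OSError(f"failed to write MEME motif to {path}: {exc}") from exc


def position_profile_from_attention(attention: np.ndarray, mask: np.ndarray,
                                    k: int, length: int,
                                    mode: str = "received") -> AttentionProfile:
    """Convenience: token saliency then projection, for one sequence."""
    token_scores = token_attention_profile(attention, mask, mode=mode)
    return AttentionProfile(
        k=k, token_scores=token_scores,
        position_scores=project_to_positions(token_scores, k, length))


def averaged_position_profile(profiles: list[AttentionProfile]) -> np.ndarray:
    """Mean per-nucleotide profile across views (per-sequence normalised)."""
    stacked = []
    for p in profiles:
        s = p.position_scores
        total = s.sum()
        stacked.append(s / total if total > 0 else s)
    return np.mean(stacked, axis=0)
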