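"""k-mer tokenization of DNA sequences and the k-mer -> index vocabulary.

A sequence of length L yields exactly ``floor((L - k) / s) + 1`` overlapping
windows of length ``k`` whose start positions are ``s`` bases apart (0-based,
half-open); trailing bases that cannot fill a window are dropped. Index 0 is
reserved for padding and out-of-vocabulary tokens (any window containing a
non-ACGT base, e.g. an N), so vocabulary indices are the positive integers
1..V.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

ALPHABET = "ACGT"
PAD_INDEX = 0


def kmer_count(length: int, k: int, s: int) -> int:
    """Number of k-mer windows in a sequence of the given length."""
    if k > length:
        raise ValueError(f"k={k} exceeds sequence length {length}")
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    return (length - k) // s + 1


@dataclass
class KmerSequence:
    """An ordered k-mer "sentence" derived from one DNA sequence."""

    tokens: list[str]
    source_id: str
    k: int
    s: int

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def split_kmers(
    sequence: str, k: int, s: int, source_id: str = ""
) -> KmerSequence:
    """Split a DNA string into its k-mer sentence with stride ``s``.

    Characters outside {A,C,G,T,N} raise an error naming the position; windows
    containing an N survive as tokens and map to the OOV index at encode time.
    """
    L = len(sequence)
    if not 1 <= k <= L:
        raise ValueError(f"need 1 <= k <= sequence length; got k={k}, L={L}")
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    for pos, base in enumerate(sequence):
        if base not in "ACGTN":
            raise ValueError(
                f"invalid base {base!r} at position {pos} in {source_id or 'sequence'}"
            )
    n = kmer_count(L, k, s)
    tokens = [sequence[t * s : t * s + k] for t in range(n)]
    return KmerSequence(tokens=tokens, source_id=source_id, k=k, s=s)


@dataclass
class KmerVocabulary:
    """Bijection between k-mers over {A,C,G,T} and contiguous indices 1..V."""

    k: int
    token_to_index: dict[str, int]
    mode: str = "full"
    index_to_token: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        indices = sorted(self.token_to_index.values())
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("indices must be contiguous 1..V with no repeats")
        for tok in self.token_to_index:
            if len(tok) != self.k or any(c not in ALPHABET for c in tok):
                raise ValueError(f"invalid token {tok!r} for k={self.k}")
        self.index_to_token = {i: t for t, i in self.token_to_index.items()}

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index


def build_vocabulary(
    k: int,
    mode: str = "full",
    corpus: Iterable[KmerSequence] | None = None,
) -> KmerVocabulary:
    """Build the k-mer index.

    ``full`` enumerates all 4**k k-mers lexicographically (indices 1..4**k) so
    every possible k-mer has an embedding at prediction time; ``observed``
    indexes only corpus k-mers, by descending frequency then lexicographic —
    intended for large k where 4**k is impractical.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if mode == "full":
        tokens = ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]
    elif mode == "observed":
        if corpus is None:
            raise ValueError("mode='observed' requires a corpus")
        counts: Counter[str] = Counter()
        for sent in corpus:
            if sent.k != k:
                raise ValueError(f"corpus sentence has k={sent.k}, expected {k}")
            counts.update(t for t in sent.tokens if all(c in ALPHABET for c in t))
        tokens = sorted(counts, key=lambda t: (-counts[t], t))
    else:
        raise ValueError(f"unknown vocabulary mode {mode!r}")
    return KmerVocabulary(
        k=k, token_to_index={t: i for i, t in enumerate(tokens, start=1)}, mode=mode
    )


def encode(
    kmer_sequence: KmerSequence, vocabulary: KmerVocabulary
) -> tuple[list[int], int]:
    """Map tokens to indices; returns ``(indices, oov_count)``.

    Out-of-vocabulary tokens (unseen k-mers or windows containing N) map to
    the reserved index 0 and are counted.
    """
    if vocabulary.k != kmer_sequence.k:
        raise ValueError(
            f"vocabulary k={vocabulary.k} != sequence k={kmer_sequence.k}"
        )
    indices, oov = [], 0
    for tok in kmer_sequence.tokens:
        idx = vocabulary.token_to_index.get(tok, PAD_INDEX)
        if idx == PAD_INDEX:
            oov += 1
        indices.append(idx)
    return indices, oov


def decode(indices: Sequence[int], vocabulary: KmerVocabulary) -> list[str]:
    """Inverse of :func:`encode` on in-vocabulary indices (index 0 rejected)."""
    tokens = []
    for idx in indices:
        if idx == PAD_INDEX:
            raise ValueError("index 0 is the padding/OOV index and cannot decode")
        if idx not in vocabulary.index_to_token:
            raise ValueError(f"index {idx} out of vocabulary range 1..{len(vocabulary)}")
        tokens.append(vocabulary.index_to_token[idx])
    return tokens
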