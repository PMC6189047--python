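"""Dense k-mer vectors learned from co-occurrence, and the embedding layer.

k-mer sentences are treated as text and a word2vec model (continuous
bag-of-words or skip-gram, trained with negative sampling) learns one
d-dimensional vector per k-mer. The trainer follows the classic word2vec
recipe: unigram^0.75 negative-sampling distribution, per-position shrunken
context windows, and a learning rate decayed linearly over the token stream.
Defaults mirror the common word2vec defaults (CBOW, window 5, 5 negatives,
5 epochs, initial rate 0.025) except that ``min_count`` is fixed at 1: rare
k-mers must keep a vector or they would become out-of-vocabulary holes at
prediction time.

The embedding layer itself supports three initialization strategies for the
classifier:

- ``no_init``        random uniform weights, fine-tuned during training;
- ``init_no_train``  pre-trained k-mer vectors, frozen;
- ``init_train``     pre-trained k-mer vectors, fine-tuned (the default).

Row 0 of every embedding matrix is the padding/out-of-vocabulary vector and
is pinned at zero; it takes no part in word2vec training and receives no
gradient in the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data_io import LabeledSequenceDataset
from .tokenizer import (
    PAD_INDEX,
    KmerSequence,
    KmerVocabulary,
    build_vocabulary,
    split_kmers,
)

STRATEGIES = ("no_init", "init_no_train", "init_train")


@dataclass(frozen=True)
class EmbeddingStrategy:
    """How the classifier's embedding layer is initialized and updated."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; choose from {STRATEGIES}")

    @property
    def source(self) -> str:
        return "uniform_random" if self.name == "no_init" else "pretrained"

    @property
    def trainable(self) -> bool:
        return self.name != "init_no_train"


@dataclass
class EmbeddingMatrix:
    """(V+1) x d lookup table of k-mer vectors; row 0 is the zero pad vector."""

    matrix: np.ndarray
    vocabulary: KmerVocabulary
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.vocabulary) + 1:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows, expected "
                f"vocabulary size + 1 = {len(self.vocabulary) + 1}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite entries")
        if np.any(self.matrix[PAD_INDEX] != 0.0):
            raise ValueError("row 0 (padding/OOV) must be the zero vector")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.vocabulary.token_to_index[token]]


def build_corpus(
    datasets: Iterable[LabeledSequenceDataset], k: int, s: int
) -> list[KmerSequence]:
    """One k-mer sentence per record across all datasets, order preserved."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset to build a corpus")
    corpus: list[KmerSequence] = []
    for ds in datasets:
        for rid, seq, _ in ds.records:
            corpus.append(split_kmers(seq, k, s, source_id=rid))
    return corpus


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_kmer_embedding(
    corpus: Sequence[KmerSequence],
    d: int = 50,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    algorithm: str = "cbow",
    vocabulary: KmerVocabulary | None = None,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> EmbeddingMatrix:
    """Train k-mer vectors on a corpus of k-mer sentences.

    Single-threaded and fully driven by ``seed``, so identical inputs give an
    element-wise identical matrix. Sentences shorter than the context window
    still train (the window is clipped at sentence edges). min_count is 1 by
    construction: every in-vocabulary k-mer keeps its vector even if rare.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus is empty")
    if d < 1:
        raise ValueError("embedding dimension d must be >= 1")
    if algorithm not in ("cbow", "skipgram"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    k = corpus[0].k
    if vocabulary is None:
        vocabulary = (
            build_vocabulary(k, "full")
            if k <= 8
            else build_vocabulary(k, "observed", corpus)
        )
    V = len(vocabulary)

    # Encode sentences once; OOV tokens (index 0) are dropped from training.
    sentences: list[np.ndarray] = []
    counts = np.zeros(V + 1, dtype=np.int64)
    for sent in corpus:
        idx = np.array(
            [vocabulary.token_to_index.get(t, PAD_INDEX) for t in sent.tokens],
            dtype=np.int64,
        )
        idx = idx[idx != PAD_INDEX]
        if idx.size:
            sentences.append(idx)
            np.add.at(counts, idx, 1)
    if not sentences:
        raise ValueError("corpus contains no in-vocabulary tokens")
    if max(len(s) for s in sentences) <= 1:
        import warnings

        warnings.warn(
            "every sentence is shorter than 2 tokens; no co-occurrence to learn"
        )

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V + 1, d)) - 0.5) / d
    W_in[PAD_INDEX] = 0.0
    W_out = np.zeros((V + 1, d))

    # Negative-sampling distribution: unigram^0.75 over indices 1..V.
    noise = counts[1:].astype(np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    def draw_negatives(n: int) -> np.ndarray:
        return np.searchsorted(noise_cdf, rng.random(n)) + 1

    total_tokens = sum(len(s) for s in sentences) * epochs
    processed = 0
    for _ in range(epochs):
        for sent in sentences:
            n = len(sent)
            reduced = rng.integers(0, window, size=n)
            for pos in range(n):
                lr = max(min_alpha, alpha * (1.0 - processed / total_tokens))
                processed += 1
                w = window - reduced[pos]
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                context = np.concatenate((sent[lo:pos], sent[pos + 1 : hi]))
                if context.size == 0:
                    continue
                center = sent[pos]
                if algorithm == "cbow":
                    h = W_in[context].mean(axis=0)
                    targets = np.concatenate(
                        ([center], draw_negatives(negative))
                    )
                    labels = np.zeros(targets.size)
                    labels[0] = 1.0
                    g = (labels - _sigmoid(W_out[targets] @ h)) * lr
                    dh = g @ W_out[targets]
                    W_out[targets] += np.outer(g, h)
                    W_in[context] += dh  # classic word2vec: mean on the forward
                    # pass, undivided update on the backward pass
                else:  # skipgram
                    v = W_in[center]
                    dv = np.zeros(d)
                    for ctx in context:
                        targets = np.concatenate(([ctx], draw_negatives(negative)))
                        labels = np.zeros(targets.size)
                        labels[0] = 1.0
                        g = (labels - _sigmoid(W_out[targets] @ v)) * lr
                        dv += g @ W_out[targets]
                        W_out[targets] += np.outer(g, v)
                    W_in[center] += dv

    W_in[PAD_INDEX] = 0.0
    provenance = {
        "source": "pretrained",
        "algorithm": algorithm,
        "d": d,
        "window": window,
        "epochs": epochs,
        "negative": negative,
        "alpha": alpha,
        "min_alpha": min_alpha,
        "min_count": 1,
        "seed": seed,
        "k": k,
        "vocabulary_mode": vocabulary.mode,
        "V": V,
        "corpus_sentences": len(sentences),
    }
    return EmbeddingMatrix(matrix=W_in, vocabulary=vocabulary, provenance=provenance)


def lookup(kmer_indices: Sequence[int], embedding: EmbeddingMatrix) -> np.ndarray:
    """Row-wise table lookup: an N x d matrix; index 0 gives the zero row."""
    idx = np.asarray(kmer_indices, dtype=np.int64)
    V = len(embedding.vocabulary)
    if idx.size and (idx.min() < 0 or idx.max() > V):
        raise IndexError(f"indices must lie in [0, {V}]")
    return embedding.matrix[idx]


@dataclass
class EmbeddingLayer:
    """Embedding-layer state as wired into the classifier."""

    weights: np.ndarray
    trainable: bool
    strategy: EmbeddingStrategy

    @property
    def V(self) -> int:
        return self.weights.shape[0] - 1

    @property
    def d(self) -> int:
        return self.weights.shape[1]


def make_embedding_layer(
    strategy: EmbeddingStrategy | str,
    pretrained: EmbeddingMatrix | None,
    V: int,
    d: int,
    seed: int = 0,
    init_scale: float = 0.05,
) -> EmbeddingLayer:
    """Initialize the classifier's embedding layer under one strategy.

    ``no_init`` draws weights from Uniform(-init_scale, +init_scale), seeded;
    the pretrained strategies copy the word2vec matrix exactly. Row 0 stays
    zero in every case.
    """
    if isinstance(strategy, str):
        strategy = EmbeddingStrategy(strategy)
    if strategy.source == "pretrained":
        if pretrained is None:
            raise ValueError(f"strategy {strategy.name} requires a pretrained matrix")
        if pretrained.matrix.shape != (V + 1, d):
            raise ValueError(
                f"pretrained matrix shape {pretrained.matrix.shape} does not "
                f"match (V+1, d) = {(V + 1, d)}"
            )
        weights = pretrained.matrix.copy()
    else:
        rng = np.random.default_rng(seed)
        weights = rng.uniform(-init_scale, init_scale, size=(V + 1, d))
        weights[PAD_INDEX] = 0.0
    return EmbeddingLayer(weights=weights, trainable=strategy.trainable, strategy=strategy)


def save_embedding(embedding: EmbeddingMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.json`` (header) + ``<prefix>.vec`` (word2vec text)."""
    prefix = Path(prefix)
    header = dict(embedding.provenance)
    header.update(
        {
            "k": embedding.vocabulary.k,
            "d": embedding.d,
            "V": len(embedding.vocabulary),
            "vocabulary_mode": embedding.vocabulary.mode,
            "orientation": "tokens-as-rows",
        }
    )
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2) + "\n")
    with open(prefix.with_suffix(".vec"), "w", encoding="ascii") as fh:
        fh.write(f"{len(embedding.vocabulary)} {embedding.d}\n")
        for idx in range(1, len(embedding.vocabulary) + 1):
            token = embedding.vocabulary.index_to_token[idx]
            vals = " ".join(repr(float(v)) for v in embedding.matrix[idx])
            fh.write(f"{token} {vals}\n")


def load_embedding(prefix: str | Path) -> EmbeddingMatrix:
    """Inverse of :func:`save_embedding`."""
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    k, d, V = header["k"], header["d"], header["V"]
    token_to_index: dict[str, int] = {}
    matrix = np.zeros((V + 1, d))
    with open(prefix.with_suffix(".vec"), "r", encoding="ascii") as fh:
        first = fh.readline().split()
        if [int(first[0]), int(first[1])] != [V, d]:
            raise ValueError("vector file shape disagrees with JSON header")
        for i, line in enumerate(fh, start=1):
            parts = line.split()
            token_to_index[parts[0]] = i
            matrix[i] = [float(x) for x in parts[1:]]
    vocab = KmerVocabulary(
        k=k, token_to_index=token_to_index, mode=header.get("vocabulary_mode", "full")
    )
    return EmbeddingMatrix(matrix=matrix, vocabulary=vocab, provenance=header)
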