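"""Synthetic ChIP-seq-style datasets: motif-bearing positives, matched negatives.

Real training data for this task are 101-bp windows centred on ChIP-seq
peaks, paired with negatives matched for length, GC content and repeat
structure. This module emulates that construction without external data: a
positive sequence is i.i.d. background with one motif instance drawn from a
position weight matrix (PWM) planted at a uniformly random offset; a
negative either

- ``composition_matched``: is drawn i.i.d. from the empirical mononucleotide
  frequencies of the positive set (matching GC content in expectation), or
- ``dinucleotide_shuffle``: is a dinucleotide-preserving (Eulerian-walk)
  shuffle of a sampled positive, which additionally preserves local repeat
  structure — the stand-in for repeat-fraction matching.

Either way a candidate negative is rejected and redrawn if it contains a
match of length >= W-1 to the motif consensus, so negatives carry no planted
signal. All randomness flows from the spec seed; identical specs produce
byte-identical FASTA output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    LabeledSequenceDataset,
    write_fasta,
    write_labels_tsv,
)

BASES = "ACGT"
NEGATIVE_MODES = ("composition_matched", "dinucleotide_shuffle")


@dataclass
class MotifModel:
    """A PWM over A,C,G,T: per-position base probabilities of the motif."""

    pwm: np.ndarray  # (W, 4), rows on the probability simplex
    name: str = "motif"

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4 or self.pwm.shape[0] < 1:
            raise ValueError("pwm must be a W x 4 matrix with W >= 1")
        if np.any(self.pwm < 0) or np.any(np.abs(self.pwm.sum(axis=1) - 1) > 1e-9):
            raise ValueError("every pwm row must be a probability distribution")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information in bits relative to uniform background."""
        p = np.clip(self.pwm, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)

    @classmethod
    def from_consensus(cls, consensus: str, strength: float = 1.0,
                       name: str | None = None) -> "MotifModel":
        """Point-mass (strength 1) or softened consensus PWM."""
        if not 0.25 <= strength <= 1.0:
            raise ValueError("strength must lie in [0.25, 1]")
        off = (1.0 - strength) / 3.0
        pwm = np.full((len(consensus), 4), off)
        for i, base in enumerate(consensus.upper()):
            pwm[i, BASES.index(base)] = strength
        return cls(pwm=pwm, name=name or f"consensus_{consensus}")


def default_motif() -> MotifModel:
    """An 8-bp consensus motif (CRE/AP-1-like TGACGTCA), full strength."""
    return MotifModel.from_consensus("TGACGTCA", strength=1.0, name="TGACGTCA")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_pos: int = 1000
    n_neg: int = 1000
    seq_length: int = 101
    motif: MotifModel = field(default_factory=default_motif)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    negative_mode: str = "composition_matched"
    plant_motif: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        bg = np.asarray(self.background, dtype=np.float64)
        if bg.shape != (4,) or np.any(bg < 0) or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        if self.negative_mode not in NEGATIVE_MODES:
            raise ValueError(f"negative_mode must be one of {NEGATIVE_MODES}")
        if self.motif.width > self.seq_length:
            raise ValueError("motif is wider than the sequence length")

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "seq_length": self.seq_length,
            "motif_name": self.motif.name,
            "motif_consensus": self.motif.consensus,
            "motif_pwm": self.motif.pwm.tolist(),
            "background": list(self.background),
            "negative_mode": self.negative_mode,
            "plant_motif": self.plant_motif,
            "seed": self.seed,
        }


def _random_sequence(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=probs))


def sample_positive(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[str, int | None]:
    """One positive sequence and its motif offset (None if planting is off)."""
    bg = np.asarray(spec.background, dtype=np.float64)
    seq = list(_random_sequence(spec.seq_length, bg, rng))
    if not spec.plant_motif:
        return "".join(seq), None
    W = spec.motif.width
    offset = int(rng.integers(0, spec.seq_length - W + 1))
    for i in range(W):
        seq[offset + i] = BASES[rng.choice(4, p=spec.motif.pwm[i])]
    return "".join(seq), offset


def _contains_consensus_match(candidate: str, consensus: str) -> bool:
    # "match" = any (W-1)-length window of the consensus, or the full string
    W = len(consensus)
    probes = {consensus} if W < 2 else {consensus, consensus[:-1], consensus[1:]}
    return any(p in candidate for p in probes)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (random Eulerian walk).

    Builds the multigraph whose edges are the observed dinucleotides and
    samples a uniform-ish Eulerian path with the last-edge arborescence
    construction: each non-terminal vertex commits one outgoing edge to a
    tree pointing at the terminal vertex, the remaining edges are shuffled.
    """
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    last = sequence[-1]
    vertices = sorted(edges.keys() | {last})
    non_terminal = [v for v in vertices if v != last and edges.get(v)]

    def reaches_terminal(last_edge: dict[str, str]) -> bool:
        for v in non_terminal:
            seen, cur = set(), v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                return False
        return True

    while True:
        last_edge = {v: edges[v][rng.integers(0, len(edges[v]))] for v in non_terminal}
        if reaches_terminal(last_edge):
            break
    shuffled: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        shuffled[v] = [rest[i] for i in order]
        if v in last_edge:
            shuffled[v].append(last_edge[v])
    out = [sequence[0]]
    pos = {v: 0 for v in shuffled}
    cur = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def sample_negative(
    spec: SyntheticSpec,
    positives: list[str],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> str:
    """One negative sequence, matched to the positives, free of the motif."""
    if not positives:
        raise ValueError("matched negative modes need a non-empty positive set")
    consensus = spec.motif.consensus
    if spec.negative_mode == "composition_matched":
        counts = np.zeros(4)
        for seq in positives:
            for i, b in enumerate(BASES):
                counts[i] += seq.count(b)
        probs = counts / counts.sum()
    for _ in range(max_attempts):
        if spec.negative_mode == "composition_matched":
            cand = _random_sequence(spec.seq_length, probs, rng)
        else:
            source = positives[rng.integers(0, len(positives))]
            cand = dinucleotide_shuffle(source, rng)
        if not (spec.plant_motif and _contains_consensus_match(cand, consensus)):
            return cand
    raise RuntimeError(
        f"could not draw a motif-free negative in {max_attempts} attempts; "
        "use a weaker/shorter motif or longer sequences"
    )


def generate_dataset(
    spec: SyntheticSpec, outdir: str | Path | None = None
) -> tuple[LabeledSequenceDataset, dict]:
    """Draw the full labeled dataset (and optionally write it to disk).

    Returns the dataset (positives label 1, negatives label 0, record order
    shuffled deterministically under the spec seed) plus truth metadata with
    the motif offset of every positive. With ``outdir`` set, writes
    ``dataset.fasta``, ``labels.tsv`` and ``metadata.json``.
    """
    rng = np.random.default_rng(spec.seed)
    positives: list[tuple[str, str, int | None]] = []
    for i in range(spec.n_pos):
        seq, offset = sample_positive(spec, rng)
        positives.append((f"pos_{i:05d}", seq, offset))
    pos_seqs = [p[1] for p in positives]
    negatives = [
        (f"neg_{i:05d}", sample_negative(spec, pos_seqs, rng))
        for i in range(spec.n_neg)
    ]
    records = [(rid, seq, 1) for rid, seq, _ in positives] + [
        (rid, seq, 0) for rid, seq in negatives
    ]
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    dataset = LabeledSequenceDataset(records=records)
    metadata = {
        "spec": spec.to_dict(),
        "motif_offsets": {rid: off for rid, _, off in positives},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([(rid, seq) for rid, seq, _ in records], outdir / "dataset.fasta")
        write_labels_tsv({rid: lab for rid, _, lab in records}, outdir / "labels.tsv")
        (outdir / "metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
    return dataset, metadata
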