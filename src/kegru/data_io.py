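"""Sequence/label I/O and reproducible dataset partitioning.

Sequences travel as plain FASTA (optionally gzipped); binary bound/unbound
labels travel in a two-column TSV (``id<TAB>label``) beside the FASTA, and an
optional convenience mode parses a trailing ``|label=0/1`` token in FASTA
headers. Genomic intervals (BED) are accepted only as provenance metadata;
sequence extraction from a genome is out of scope.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPLITS = ("train", "validation", "test")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the expected format."""


@dataclass
class LabeledSequenceDataset:
    """DNA sequences with binary bound/unbound labels and a split assignment.

    ``records`` is a list of ``(id, sequence, label)`` triples; ``partition``
    maps every record id to one of ``train``/``validation``/``test`` once
    :func:`split_dataset` has run.
    """

    records: list[tuple[str, str, int]]
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        for rid, seq, label in self.records:
            if label not in (0, 1):
                raise ValueError(f"label for {rid!r} must be 0 or 1, got {label!r}")
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
        if self.partition:
            extra = set(self.partition) - set(ids)
            missing = set(ids) - set(self.partition)
            if extra or missing:
                raise ValueError(
                    f"partition does not cover records exactly once "
                    f"(missing={sorted(missing)}, extra={sorted(extra)})"
                )
            bad = {s for s in self.partition.values() if s not in SPLITS}
            if bad:
                raise ValueError(f"unknown split names: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def labels(self) -> dict[str, int]:
        return {rid: lab for rid, _, lab in self.records}

    def subset(self, split: str) -> list[tuple[str, str, int]]:
        """Records assigned to one split, in dataset order."""
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        if not self.partition:
            raise ValueError("dataset has no partition; call split_dataset first")
        return [r for r in self.records if self.partition[r[0]] == split]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` in file order.

    Multi-line records are joined and whitespace stripped. A file whose first
    non-blank line is not a ``>`` header, or an empty file, raises
    :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # Bio.SeqIO silently ignores text before the first header, so enforce
    # strictness up front with line numbers for the error message.
    with _open_text(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line.rstrip("\n"))
                break
        if first is None:
            raise FastaFormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FastaFormatError(
                f"{path}: line {first[0]} is not a FASTA header: {first[1]!r}"
            )
    with _open_text(path) as fh:
        records = [
            (rec.id, str(rec.seq).upper().replace(" ", ""))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA; round-trips with read_fasta."""
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w", encoding="ascii") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read an ``id<TAB>label`` TSV into a label map (header row optional)."""
    labels: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith("id\t")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            rid, lab = parts
            if lab not in ("0", "1"):
                raise ValueError(f"{path}: line {lineno}: label must be 0 or 1")
            if rid in labels:
                raise ValueError(f"{path}: line {lineno}: duplicate id {rid!r}")
            labels[rid] = int(lab)
    return labels


def write_labels_tsv(labels: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for rid, lab in labels.items():
            fh.write(f"{rid}\t{lab}\n")


def parse_header_labels(records: Sequence[tuple[str, str]]) -> dict[str, int]:
    """Extract labels from FASTA ids of the form ``name|label=0`` or ``=1``."""
    labels: dict[str, int] = {}
    for rid, _ in records:
        if "|label=" not in rid:
            raise ValueError(f"record {rid!r} carries no |label= token")
        name, _, lab = rid.rpartition("|label=")
        if lab not in ("0", "1"):
            raise ValueError(f"record {rid!r}: label must be 0 or 1")
        labels[rid] = int(lab)
    return labels


def attach_labels(
    records: Sequence[tuple[str, str]], labels: Mapping[str, int]
) -> LabeledSequenceDataset:
    """Join records with a label map into a validated dataset.

    Every record id must appear in ``labels``; missing ids are reported
    together in the error.
    """
    missing = [rid for rid, _ in records if rid not in labels]
    if missing:
        raise ValueError(f"records without labels: {missing}")
    triples = [(rid, seq, labels[rid]) for rid, seq in records]
    return LabeledSequenceDataset(records=triples)


def split_dataset(
    dataset: LabeledSequenceDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> LabeledSequenceDataset:
    """Assign records to train/validation/test, stratified by label.

    Split sizes are ``floor(fraction * n)`` with the remainder going to train;
    within each label class the same rule applies so balanced inputs yield
    approximately balanced splits. Identical seeds give identical partitions.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, validation, test)")
    if any(f <= 0 for f in fractions):
        raise ValueError(f"all fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    rng = np.random.default_rng(seed)
    n = len(dataset.records)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))

    by_label: dict[int, list[str]] = {}
    for rid, _, lab in dataset.records:
        by_label.setdefault(lab, []).append(rid)
    classes = sorted(by_label)
    for lab in classes:
        ids = by_label[lab]
        order = rng.permutation(len(ids))
        by_label[lab] = [ids[i] for i in order]

    def apportion(total: int) -> dict[int, int]:
        # Largest-remainder apportionment of `total` slots across classes,
        # proportional to class size; keeps global split sizes exact while
        # stratifying. Ties break toward the larger class then lower label.
        quotas = {lab: total * len(by_label[lab]) / n for lab in classes}
        counts = {lab: int(np.floor(quotas[lab])) for lab in classes}
        leftover = total - sum(counts.values())
        order = sorted(
            classes,
            key=lambda lab: (-(quotas[lab] - counts[lab]), -len(by_label[lab]), lab),
        )
        for lab in order[:leftover]:
            counts[lab] += 1
        return counts

    val_counts = apportion(n_val)
    test_counts = apportion(n_test)

    # Repair: a tiny class can be over-allocated by the remainder step; move
    # the excess to the class with the most spare capacity (global sizes kept).
    def spare(lab: int) -> int:
        return len(by_label[lab]) - val_counts[lab] - test_counts[lab]

    for lab in classes:
        while spare(lab) < 0:
            counts = test_counts if test_counts[lab] > 0 else val_counts
            counts[lab] -= 1
            others = [c for c in classes if c != lab]
            if not others or max(spare(c) for c in others) <= 0:
                raise ValueError("fractions cannot be satisfied for these labels")
            counts[max(others, key=spare)] += 1

    partition: dict[str, str] = {}
    for lab in classes:
        ids = by_label[lab]
        c_val, c_test = val_counts[lab], test_counts[lab]
        c_train = len(ids) - c_val - c_test
        for i, rid in enumerate(ids):
            if i < c_train:
                partition[rid] = "train"
            elif i < c_train + c_val:
                partition[rid] = "validation"
            else:
                partition[rid] = "test"
    return LabeledSequenceDataset(records=list(dataset.records), partition=partition)


def write_partition_tsv(dataset: LabeledSequenceDataset, path: str | Path) -> None:
    """Write the ``id<TAB>split`` manifest beside outputs for reproducibility."""
    with open(path, "w", encoding="ascii") as fh:
        for rid in dataset.ids:
            fh.write(f"{rid}\t{dataset.partition[rid]}\n")


def read_partition_tsv(path: str | Path) -> dict[str, str]:
    part: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            rid, _, split = line.partition("\t")
            if split not in SPLITS:
                raise ValueError(f"{path}: line {lineno}: unknown split {split!r}")
            part[rid] = split
    return part
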