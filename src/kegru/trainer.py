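"""Training, evaluation and the hyper-parameter experiments.

The default hyper-parameter grid is the 3 x 4 cross of GRU unit counts
{50, 80, 100} with optimizers {SGD, Adam, Adagrad, RMSprop}, trained with
mini-batches of 200 sequences. Models are scored with AUC (probability that
a random positive outranks a random negative, ties 0.5) and APS (average
precision: the weighted mean of precisions at each threshold, weighted by
recall increments); both are computed on raw sigmoid scores, delegated to
scikit-learn. The epoch budget and early stopping (patience on validation
AUC, best-epoch weight restoration) are this package's own protocol: the
train/validation workflow implies a validation-driven stop but fixes no
schedule. Optimizer learning rates default to the framework-conventional
values recorded in ``DEFAULT_LEARNING_RATES``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import LabeledSequenceDataset
from .embedding import (
    EmbeddingMatrix,
    EmbeddingStrategy,
    build_corpus,
    make_embedding_layer,
    train_kmer_embedding,
)
from .gru_model import BiGRUClassifier, pad_batch
from .tokenizer import KmerVocabulary, build_vocabulary, encode, split_kmers

GRID_UNITS = (50, 80, 100)
GRID_OPTIMIZERS = ("SGD", "Adam", "Adagrad", "RMSprop")
DEFAULT_LEARNING_RATES = {"SGD": 0.01, "Adam": 0.001, "Adagrad": 0.01, "RMSprop": 0.001}


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    """Base mini-batch gradient-descent optimizer over a flat param dict."""

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


class Adagrad(Optimizer):
    def __init__(self, lr: float = 0.01, eps: float = 1e-7):
        super().__init__(lr)
        self.eps = eps
        self._acc: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            acc = self._acc.setdefault(k, np.zeros_like(g))
            acc += g * g
            params[k] -= self.lr * g / (np.sqrt(acc) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps
        self._acc: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            acc = self._acc.setdefault(k, np.zeros_like(g))
            acc *= self.rho
            acc += (1.0 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(acc) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params, grads):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            m = self._m.setdefault(k, np.zeros_like(g))
            v = self._v.setdefault(k, np.zeros_like(g))
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / (1.0 - b1 ** self._t)
            vhat = v / (1.0 - b2 ** self._t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS: dict[str, Callable[[float], Optimizer]] = {
    "SGD": SGD, "Adam": Adam, "Adagrad": Adagrad, "RMSprop": RMSprop,
}


def make_optimizer(name: str, lr: float | None = None) -> Optimizer:
    if name not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {GRID_OPTIMIZERS}")
    return OPTIMIZERS[name](lr if lr is not None else DEFAULT_LEARNING_RATES[name])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given label set."""


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; ties count one half.

    Equals the Mann-Whitney U statistic normalized by (#positives x
    #negatives). Requires at least one positive and one negative label.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC needs both a positive and a negative label")
    return float(roc_auc_score(y, s))


def aps(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision: sum over thresholds of (R_n - R_{n-1}) * P_n."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.any(y == 1):
        raise UndefinedMetricError("APS needs at least one positive label")
    return float(average_precision_score(y, s))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """One cell of the hyper-parameter space."""

    units: int = 50
    optimizer: str = "Adam"
    batch_size: int = 200
    epochs: int = 20
    learning_rate: float | None = None
    embedding_strategy: str = "init_train"
    k: int = 5
    s: int = 2
    d: int = 50
    merge_mode: str = "concatenate"
    num_layers: int = 1
    head_input: str = "final"
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        EmbeddingStrategy(self.embedding_strategy)  # validates the name

    @property
    def effective_lr(self) -> float:
        return (self.learning_rate if self.learning_rate is not None
                else DEFAULT_LEARNING_RATES[self.optimizer])


def default_grid(base: TrainConfig | None = None) -> list[TrainConfig]:
    """The 12-cell default grid: units {50,80,100} x the four optimizers."""
    base = base or TrainConfig()
    return [
        replace(base, units=u, optimizer=opt)
        for u in GRID_UNITS
        for opt in GRID_OPTIMIZERS
    ]


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------

def encode_dataset(
    dataset: LabeledSequenceDataset,
    vocabulary: KmerVocabulary,
    k: int,
    s: int,
) -> dict[str, tuple[list[list[int]], np.ndarray]]:
    """Tokenize + encode every record, grouped by split."""
    out: dict[str, tuple[list[list[int]], list[int]]] = {}
    for split in ("train", "validation", "test"):
        seqs, ys = [], []
        for rid, seq, label in dataset.subset(split):
            idx, _ = encode(split_kmers(seq, k, s, source_id=rid), vocabulary)
            seqs.append(idx)
            ys.append(label)
        out[split] = (seqs, np.asarray(ys))
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class TrainingDivergedError(RuntimeError):
    pass


def _snapshot(model: BiGRUClassifier) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in model.param_dict().items()}


def _restore(model: BiGRUClassifier, snap: dict[str, np.ndarray]) -> None:
    for k, v in model.param_dict().items():
        v[...] = snap[k]


def train(
    model: BiGRUClassifier,
    data: dict[str, tuple[list[list[int]], np.ndarray]],
    config: TrainConfig,
) -> tuple[BiGRUClassifier, list[dict]]:
    """Mini-batch maximum-likelihood training with validation-AUC early stop.

    ``data`` maps split names to (encoded sequences, labels); train and
    validation must be non-empty. Logs one dict per epoch (train loss,
    validation AUC/APS) and restores the best-validation-AUC weights at the
    end. A fixed config seed reproduces the whole loss trajectory.
    """
    train_x, train_y = data["train"]
    val_x, val_y = data["validation"]
    if not train_x or not val_x:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed + 1)  # batch-order stream
    opt = make_optimizer(config.optimizer, config.learning_rate)
    log: list[dict] = []
    best_auc, best_snap, best_epoch, stall = -np.inf, None, -1, 0
    params = model.param_dict()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_x))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            idx, mask = pad_batch([train_x[i] for i in batch])
            loss_val, _, grads = model.forward_backward(idx, mask, train_y[batch])
            if not np.isfinite(loss_val):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            opt.step(params, grads)
            losses.append(loss_val)
        val_scores = model.predict_proba_batch(val_x)
        entry = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "val_auc": auc(val_scores, val_y),
            "val_aps": aps(val_scores, val_y),
        }
        log.append(entry)
        if entry["val_auc"] > best_auc:
            best_auc, best_snap, best_epoch = entry["val_auc"], _snapshot(model), epoch
            stall = 0
        else:
            stall += 1
            if config.patience and stall >= config.patience:
                break
    if best_snap is not None:
        _restore(model, best_snap)
    log.append({"best_epoch": best_epoch + 1, "best_val_auc": best_auc})
    return model, log


def evaluate(
    model: BiGRUClassifier,
    data: dict[str, tuple[list[list[int]], np.ndarray]],
    split: str = "test",
) -> dict[str, float]:
    xs, ys = data[split]
    scores = model.predict_proba_batch(xs)
    return {"auc": auc(scores, ys), "aps": aps(scores, ys), "split": split}


def run_experiment(
    dataset: LabeledSequenceDataset,
    config: TrainConfig,
    pretrained: EmbeddingMatrix | None = None,
    embedding_epochs: int = 5,
    embedding_window: int = 5,
) -> tuple[BiGRUClassifier, dict, list[dict]]:
    """Tokenize, embed, train and test one configuration end to end.

    If the strategy needs pre-trained vectors and none are supplied, word2vec
    runs on the k-mer corpus of this dataset first. Returns (model, metrics
    dict with validation and test AUC/APS, training log).
    """
    strategy = EmbeddingStrategy(config.embedding_strategy)
    if pretrained is not None:
        vocabulary = pretrained.vocabulary
        if vocabulary.k != config.k or pretrained.d != config.d:
            raise ValueError("pretrained embedding does not match config k/d")
    elif strategy.source == "pretrained":
        corpus = build_corpus([dataset], config.k, config.s)
        pretrained = train_kmer_embedding(
            corpus, d=config.d, window=embedding_window, epochs=embedding_epochs,
            seed=config.seed + 2,
        )
        vocabulary = pretrained.vocabulary
    else:
        vocabulary = build_vocabulary(config.k, "full")
    data = encode_dataset(dataset, vocabulary, config.k, config.s)
    layer = make_embedding_layer(
        strategy, pretrained, V=len(vocabulary), d=config.d, seed=config.seed + 3
    )
    model = BiGRUClassifier.initialize(
        units=config.units,
        embedding=layer,
        merge_mode=config.merge_mode,
        num_layers=config.num_layers,
        seed=config.seed + 4,
        head_input=config.head_input,
    )
    model, log = train(model, data, config)
    metrics = {
        "validation": evaluate(model, data, "validation"),
        "test": evaluate(model, data, "test"),
    }
    return model, metrics, log


# ---------------------------------------------------------------------------
# Reports, grid search, ablation, sensitivity
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Flat rows of per-configuration metrics; serializes to TSV/JSON."""

    rows: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.rows, indent=2, default=str) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        return cls(rows=json.loads(Path(path).read_text()))

    def to_tsv(self, path: str | Path) -> None:
        if not self.rows:
            Path(path).write_text("")
            return
        cols = list(self.rows[0].keys())
        lines = ["\t".join(cols)]
        for row in self.rows:
            lines.append("\t".join(str(row.get(c, "")) for c in cols))
        Path(path).write_text("\n".join(lines) + "\n")


def _config_row(config: TrainConfig) -> dict:
    return asdict(config)


def grid_search(
    dataset: LabeledSequenceDataset,
    grid: Sequence[TrainConfig] | None = None,
    dataset_id: str = "dataset",
    pretrained: EmbeddingMatrix | None = None,
) -> tuple[EvaluationReport, TrainConfig | None]:
    """Train every grid cell; pick argmax validation AUC.

    Ties break toward higher validation APS, then fewer units. Failing cells
    are flagged in the report and do not abort the remaining cells. The
    pre-trained embedding is shared across cells (all default-grid cells use
    the same k, s, d).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    if pretrained is None and any(
        EmbeddingStrategy(c.embedding_strategy).source == "pretrained" for c in grid
    ):
        c0 = grid[0]
        corpus = build_corpus([dataset], c0.k, c0.s)
        pretrained = train_kmer_embedding(
            corpus, d=c0.d, window=5, epochs=5, seed=c0.seed + 2
        )
    report = EvaluationReport()
    for config in grid:
        row = {"dataset": dataset_id, **_config_row(config)}
        try:
            cell_pre = (
                pretrained
                if pretrained is not None
                and pretrained.vocabulary.k == config.k
                and pretrained.d == config.d
                else None
            )
            _, metrics, log = run_experiment(dataset, config, pretrained=cell_pre)
            row.update(
                {
                    "val_auc": metrics["validation"]["auc"],
                    "val_aps": metrics["validation"]["aps"],
                    "test_auc": metrics["test"]["auc"],
                    "test_aps": metrics["test"]["aps"],
                    "failed": False,
                }
            )
        except Exception as exc:  # noqa: BLE001 -- cells fail independently
            row.update({"failed": True, "error": f"{type(exc).__name__}: {exc}"})
        report.rows.append(row)
    ok = [r for r in report.rows if not r["failed"]]
    if not ok:
        return report, None
    best_row = max(ok, key=lambda r: (r["val_auc"], r["val_aps"], -r["units"]))
    best = next(
        c for c in grid
        if c.units == best_row["units"] and c.optimizer == best_row["optimizer"]
    )
    return report, best


def compare_embedding_strategies(
    dataset: LabeledSequenceDataset,
    base_config: TrainConfig,
    pretrained: EmbeddingMatrix | None = None,
    dataset_id: str = "dataset",
) -> EvaluationReport:
    """Train once per embedding strategy with otherwise identical settings."""
    if pretrained is None:
        corpus = build_corpus([dataset], base_config.k, base_config.s)
        pretrained = train_kmer_embedding(
            corpus, d=base_config.d, window=5, epochs=5, seed=base_config.seed + 2
        )
    report = EvaluationReport()
    for name in ("no_init", "init_no_train", "init_train"):
        config = replace(base_config, embedding_strategy=name)
        _, metrics, _ = run_experiment(dataset, config, pretrained=pretrained)
        report.rows.append(
            {
                "dataset": dataset_id,
                "strategy": name,
                **_config_row(config),
                "val_auc": metrics["validation"]["auc"],
                "val_aps": metrics["validation"]["aps"],
                "test_auc": metrics["test"]["auc"],
                "test_aps": metrics["test"]["aps"],
            }
        )
    return report


def sensitivity_sweep(
    dataset: LabeledSequenceDataset,
    axis: str,
    values: Sequence[int],
    base_config: TrainConfig | None = None,
    n_seeds: int = 1,
    dataset_id: str = "dataset",
) -> EvaluationReport:
    """Sweep one of k / s / d, retraining tokenizer+embedding per value.

    k and s change the corpus so the embedding re-trains; d changes only the
    embedding width. Reports mean and median test AUC per value over
    ``n_seeds`` repeats.
    """
    if axis not in ("k", "s", "d"):
        raise ValueError("axis must be one of 'k', 's', 'd'")
    base_config = base_config or TrainConfig()
    report = EvaluationReport()
    for value in values:
        aucs, apss = [], []
        for i in range(n_seeds):
            config = replace(base_config, **{axis: value, "seed": base_config.seed + i})
            _, metrics, _ = run_experiment(dataset, config)
            aucs.append(metrics["test"]["auc"])
            apss.append(metrics["test"]["aps"])
        report.rows.append(
            {
                "dataset": dataset_id,
                "axis": axis,
                "value": value,
                "vocab_size": 4 ** (value if axis == "k" else base_config.k),
                "mean_auc": float(np.mean(aucs)),
                "median_auc": float(np.median(aucs)),
                "mean_aps": float(np.mean(apss)),
                "n_seeds": n_seeds,
            }
        )
    return report
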