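"""Metrics against brute-force oracles, training behaviour, grid and reports."""

import numpy as np
import pytest

from kegru.embedding import build_corpus, train_kmer_embedding
from kegru.trainer import (
    EvaluationReport,
    TrainConfig,
    UndefinedMetricError,
    aps,
    auc,
    compare_embedding_strategies,
    default_grid,
    encode_dataset,
    grid_search,
    make_optimizer,
    run_experiment,
    sensitivity_sweep,
    train,
)


# -- independent metric oracles ---------------------------------------------

def auc_by_pair_counting(scores, labels):
    """Exhaustive positive/negative pair comparison; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aps_by_pr_step_sum(scores, labels):
    """Exact precision-recall step sum over descending score thresholds."""
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    n_pos = int(y.sum())
    out, tp, prev_recall, i = 0.0, 0, 0.0, 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # one threshold per distinct score
            j += 1
        tp += int(y[i:j].sum())
        precision = tp / j
        recall = tp / n_pos
        out += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return out


class TestMetrics:
    def test_auc_perfect_separation(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_auc_all_ties_is_half(self):
        assert auc([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0]) == 0.5

    def test_auc_worked_example_three_quarters(self):
        assert auc([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_auc_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.9], [1, 1])

    def test_aps_perfect_ranking(self):
        assert aps([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_aps_worst_ranking_single_positive(self):
        assert aps([0.2, 0.9], [1, 0]) == 0.5

    def test_aps_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            aps([0.5, 0.6], [0, 0])

    def test_metrics_match_brute_force_200_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            # discretized scores force ties to exercise the 0.5 convention
            scores = np.round(rng.random(n), 2)
            assert auc(scores, labels) == pytest.approx(
                auc_by_pair_counting(scores, labels), abs=1e-12
            )
            assert aps(scores, labels) == pytest.approx(
                aps_by_pr_step_sum(scores, labels), abs=1e-12
            )


class TestConfig:
    def test_default_grid_is_twelve_cells(self):
        grid = default_grid()
        assert len(grid) == 12
        assert {c.units for c in grid} == {50, 80, 100}
        assert {c.optimizer for c in grid} == {"SGD", "Adam", "Adagrad", "RMSprop"}

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(optimizer="LBFGS")

    def test_per_optimizer_default_learning_rates(self):
        assert TrainConfig(optimizer="SGD").effective_lr == 0.01
        assert TrainConfig(optimizer="Adam").effective_lr == 0.001


class TestOptimizers:
    @pytest.mark.parametrize("name", ["SGD", "Adam", "Adagrad", "RMSprop"])
    def test_descends_on_quadratic(self, name):
        params = {"w": np.array([5.0, -3.0])}
        opt = make_optimizer(name)
        for _ in range(200):
            opt.step(params, {"w": 2.0 * params["w"]})
        assert np.linalg.norm(params["w"]) < np.linalg.norm([5.0, -3.0])


class TestTraining:
    def test_loss_decreases_on_separable_data(self, tiny_dataset, fast_config):
        _, metrics, log = run_experiment(tiny_dataset, fast_config)
        epochs = [e for e in log if "train_loss" in e]
        assert epochs[-1]["train_loss"] < epochs[0]["train_loss"]
        assert 0.0 <= metrics["test"]["auc"] <= 1.0

    def test_fixed_seed_reproduces_epoch_losses(self, tiny_dataset, fast_config):
        _, _, log_a = run_experiment(tiny_dataset, fast_config)
        _, _, log_b = run_experiment(tiny_dataset, fast_config)
        la = [e["train_loss"] for e in log_a if "train_loss" in e]
        lb = [e["train_loss"] for e in log_b if "train_loss" in e]
        np.testing.assert_allclose(la, lb, atol=1e-6)

    def test_empty_validation_rejected(self, fast_config):
        data = {"train": ([[1, 2]], np.array([1])), "validation": ([], np.array([]))}
        from kegru.gru_model import BiGRUClassifier
        from kegru.embedding import make_embedding_layer

        layer = make_embedding_layer("no_init", None, V=16, d=4, seed=0)
        model = BiGRUClassifier.initialize(4, layer, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, data, fast_config)


@pytest.fixture(scope="module")
def small_grid_result(tiny_dataset, fast_config):
    from dataclasses import replace

    grid = [replace(fast_config, units=4, optimizer=o, epochs=1)
            for o in ("Adam", "SGD")]
    return grid_search(tiny_dataset, grid), grid


class TestGridSearch:
    def test_one_report_row_per_cell(self, small_grid_result):
        (report, best), grid = small_grid_result
        assert len(report.rows) == len(grid)
        assert best is not None

    def test_best_is_validation_auc_argmax(self, small_grid_result):
        (report, best), _ = small_grid_result
        ok = [r for r in report.rows if not r["failed"]]
        top = max(ok, key=lambda r: (r["val_auc"], r["val_aps"], -r["units"]))
        assert best.optimizer == top["optimizer"] and best.units == top["units"]

    def test_report_roundtrips(self, small_grid_result, tmp_path):
        (report, _), _ = small_grid_result
        report.to_json(tmp_path / "r.json")
        back = EvaluationReport.from_json(tmp_path / "r.json")
        assert back.rows == report.rows
        report.to_tsv(tmp_path / "r.tsv")
        lines = (tmp_path / "r.tsv").read_text().strip().split("\n")
        assert len(lines) == len(report.rows) + 1  # header + one per cell


@pytest.fixture(scope="module")
def ablation(tiny_dataset, fast_config):
    corpus = build_corpus([tiny_dataset], fast_config.k, fast_config.s)
    pretrained = train_kmer_embedding(corpus, d=fast_config.d, epochs=1, seed=1)
    frozen_before = pretrained.matrix.copy()
    report = compare_embedding_strategies(tiny_dataset, fast_config, pretrained)
    return report, pretrained, frozen_before


class TestEmbeddingStrategyComparison:
    def test_exactly_three_rows(self, ablation):
        report, _, _ = ablation
        assert [r["strategy"] for r in report.rows] == [
            "no_init", "init_no_train", "init_train"
        ]

    def test_pretrained_matrix_unmodified_by_ablation(self, ablation):
        _, pretrained, before = ablation
        np.testing.assert_array_equal(pretrained.matrix, before)

    def test_metrics_are_valid_probabilities(self, ablation):
        report, _, _ = ablation
        for row in report.rows:
            assert 0.0 <= row["val_auc"] <= 1.0
            assert 0.0 <= row["test_aps"] <= 1.0


def test_sensitivity_sweep_rows_and_vocab(tiny_dataset, fast_config):
    from dataclasses import replace

    cfg = replace(fast_config, epochs=1)
    report = sensitivity_sweep(tiny_dataset, "k", [4, 5], cfg)
    assert [r["value"] for r in report.rows] == [4, 5]
    assert [r["vocab_size"] for r in report.rows] == [256, 1024]
    assert all(np.isfinite(r["mean_auc"]) for r in report.rows)
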