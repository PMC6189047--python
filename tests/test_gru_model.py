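"""GRU recurrence correctness, bidirectional merging, masking and the loss."""

import math

import numpy as np
import pytest

from kegru.embedding import EmbeddingLayer, EmbeddingStrategy
from kegru.gru_model import (
    BiGRUClassifier,
    GRUCellParams,
    gru_step,
    loss,
    pad_batch,
    predict_proba,
    run_bigru,
)


def scalar_gru_step(x, h_prev, p):
    """Straight-line scalar re-implementation of the gate equations."""
    units, d = p.units, p.d
    h_next = [0.0] * units
    for i in range(units):
        az = p.b_z[i] + sum(p.W_z[i][j] * x[j] for j in range(d)) \
            + sum(p.U_z[i][j] * h_prev[j] for j in range(units))
        ar = p.b_r[i] + sum(p.W_r[i][j] * x[j] for j in range(d)) \
            + sum(p.U_r[i][j] * h_prev[j] for j in range(units))
        z = 1.0 / (1.0 + math.exp(-az))
        r_row = 1.0 / (1.0 + math.exp(-ar))
        h_next[i] = (z, r_row)
    # reset gate applies element-wise to h_prev before the recurrent matmul
    r = [h_next[i][1] for i in range(units)]
    out = [0.0] * units
    for i in range(units):
        am = p.b_h[i] + sum(p.W_h[i][j] * x[j] for j in range(d)) \
            + sum(p.U_h[i][j] * r[j] * h_prev[j] for j in range(units))
        m = math.tanh(am)
        z = h_next[i][0]
        out[i] = (1.0 - z) * h_prev[i] + z * m
    return np.array(out)


def random_params(units, d, rng, scale=1.0):
    def m(*shape):
        return rng.normal(scale=scale, size=shape)

    return GRUCellParams(
        W_z=m(units, d), U_z=m(units, units), b_z=m(units),
        W_r=m(units, d), U_r=m(units, units), b_r=m(units),
        W_h=m(units, d), U_h=m(units, units), b_h=m(units),
    )


def make_model(units=4, d=3, V=20, merge_mode="concatenate", seed=0,
               num_layers=1, head_input="final", trainable=True):
    rng = np.random.default_rng(seed)
    w = rng.normal(scale=0.5, size=(V + 1, d))
    w[0] = 0.0
    layer = EmbeddingLayer(weights=w, trainable=trainable,
                           strategy=EmbeddingStrategy("no_init"))
    return BiGRUClassifier.initialize(units, layer, merge_mode=merge_mode,
                                      num_layers=num_layers, seed=seed + 1,
                                      head_input=head_input)


class TestGruStep:
    def test_zero_parameters_halve_previous_state(self, rng):
        p = random_params(4, 3, rng, scale=0.0)
        h_prev = rng.normal(size=4)
        np.testing.assert_allclose(
            gru_step(rng.normal(size=3), h_prev, p), 0.5 * h_prev
        )

    def test_all_zero_inputs_give_zero_state(self):
        p = GRUCellParams(**{k: np.ones((1, 1)) if k.startswith(("W", "U"))
                             else np.zeros(1)
                             for k in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r",
                                       "W_h", "U_h", "b_h")})
        assert gru_step(np.zeros(1), np.zeros(1), p) == pytest.approx(0.0)

    def test_scalar_hand_evaluation(self):
        """units=1, d=1, unit weights, x=h=1, checked against a hand derivation."""
        p = GRUCellParams(**{k: np.ones((1, 1)) if k.startswith(("W", "U"))
                             else np.zeros(1)
                             for k in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r",
                                       "W_h", "U_h", "b_h")})
        z = 1.0 / (1.0 + math.exp(-2.0))  # sigmoid(1*1 + 1*1)
        assert z == pytest.approx(0.880797, abs=1e-6)
        m = math.tanh(1.0 + z)            # reset gate also sigmoid(2)
        expected = (1.0 - z) * 1.0 + z * m
        got = gru_step(np.array([1.0]), np.array([1.0]), p)
        np.testing.assert_allclose(got, [expected], atol=1e-12)

    def test_matches_scalar_oracle_200_trials(self, rng):
        for _ in range(200):
            units, d = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            p = random_params(units, d, rng)
            x, h = rng.normal(size=d), rng.normal(size=units)
            np.testing.assert_allclose(
                gru_step(x, h, p), scalar_gru_step(x, h, p), atol=1e-6
            )

    def test_shape_mismatch_rejected(self, rng):
        p = random_params(3, 2, rng)
        with pytest.raises(ValueError):
            gru_step(np.zeros(3), np.zeros(3), p)

    def test_nonfinite_input_rejected(self, rng):
        p = random_params(2, 2, rng)
        with pytest.raises(ValueError):
            gru_step(np.array([np.nan, 0.0]), np.zeros(2), p)


class TestGateDegeneracies:
    def test_update_gate_zero_freezes_state(self, rng):
        p = random_params(3, 2, rng)
        p.b_z[:] = -1e9
        h_prev = rng.normal(size=3)
        np.testing.assert_allclose(gru_step(rng.normal(size=2), h_prev, p), h_prev)

    def test_update_gate_one_takes_candidate(self, rng):
        p = random_params(3, 2, rng)
        p.b_z[:] = 1e9
        x, h_prev = rng.normal(size=2), rng.normal(size=3)
        r = 1.0 / (1.0 + np.exp(-(p.W_r @ x + p.U_r @ h_prev + p.b_r)))
        m = np.tanh(p.W_h @ x + p.U_h @ (r * h_prev) + p.b_h)
        np.testing.assert_allclose(gru_step(x, h_prev, p), m)

    def test_boundedness_100_trials(self, rng):
        """|h_t| <= 1 whenever |h_0| <= 1: h_t is a convex mix with tanh output."""
        for _ in range(100):
            units, d = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = random_params(units, d, rng, scale=3.0)
            h = rng.uniform(-1, 1, size=units)
            for _ in range(5):
                h = gru_step(rng.normal(size=d), h, p)
                assert np.all(np.abs(h) <= 1.0)


class TestRunBigru:
    def test_single_step_directions_agree(self, rng):
        model = make_model(units=3, merge_mode="sum", seed=2)
        x = rng.normal(size=(1, model.embedding.d))
        fwd, bwd = model.layers[0]
        bwd.W_z[...] = fwd.W_z; bwd.U_z[...] = fwd.U_z; bwd.b_z[...] = fwd.b_z
        bwd.W_r[...] = fwd.W_r; bwd.U_r[...] = fwd.U_r; bwd.b_r[...] = fwd.b_r
        bwd.W_h[...] = fwd.W_h; bwd.U_h[...] = fwd.U_h; bwd.b_h[...] = fwd.b_h
        out = run_bigru(x, np.array([True]), model)
        fout = gru_step(x[0], np.zeros(3), fwd)
        np.testing.assert_allclose(out, 2 * fout)

    def test_concatenate_dimension(self, rng):
        model = make_model(units=50, d=8, seed=3)
        x = rng.normal(size=(5, 8))
        assert run_bigru(x, np.ones(5, bool), model).shape == (100,)

    def test_padding_steps_do_not_change_output(self, rng):
        model = make_model(units=4, d=3, seed=4)
        x = rng.normal(size=(6, 3))
        base = run_bigru(x, np.ones(6, bool), model)
        for pad in (1, 3, 10):
            xp = np.vstack([x, np.zeros((pad, 3))])
            mp = np.concatenate([np.ones(6, bool), np.zeros(pad, bool)])
            np.testing.assert_array_equal(run_bigru(xp, mp, model), base)

    def test_all_masked_rejected(self, rng):
        model = make_model()
        with pytest.raises(ValueError, match="masked"):
            run_bigru(rng.normal(size=(3, 3)), np.zeros(3, bool), model)

    def test_merge_average_is_half_sum(self, rng):
        ms = make_model(units=4, d=3, merge_mode="sum", seed=5)
        ma = make_model(units=4, d=3, merge_mode="average", seed=5)
        x = rng.normal(size=(7, 3))
        np.testing.assert_allclose(
            run_bigru(x, np.ones(7, bool), ma),
            run_bigru(x, np.ones(7, bool), ms) / 2.0,
        )


class TestPredictProba:
    def test_zero_head_gives_half(self):
        model = make_model(seed=6)
        model.head_beta[:] = 0.0
        model.head_bias[:] = 0.0
        assert predict_proba([1, 2, 3], model) == pytest.approx(0.5)

    def test_monotone_in_bias(self):
        model = make_model(seed=7)
        probs = []
        for bias in (-2.0, 0.0, 2.0):
            model.head_bias[:] = bias
            probs.append(predict_proba([4, 5], model))
        assert probs[0] < probs[1] < probs[2]

    def test_batch_equals_single(self, rng):
        model = make_model(units=5, d=4, V=30, seed=8)
        seqs = [list(rng.integers(1, 31, size=rng.integers(2, 9))) for _ in range(10)]
        batch = model.predict_proba_batch(seqs)
        singles = [predict_proba(s, model) for s in seqs]
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_probability_in_open_interval(self, rng):
        model = make_model(seed=9)
        p = predict_proba(list(rng.integers(1, 21, size=12)), model)
        assert 0.0 < p < 1.0


class TestLoss:
    def test_half_probability_positive_label(self):
        assert loss([0.5], [1]) == pytest.approx(math.log(2), abs=1e-6)

    def test_perfect_prediction_near_zero(self):
        assert loss([1.0 - 1e-7], [1]) == pytest.approx(0.0, abs=1e-6)

    def test_two_term_hand_evaluation(self):
        assert loss([0.9, 0.1], [1, 0]) == pytest.approx(0.210721, abs=1e-6)

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(loss([0.0, 1.0], [1, 0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss([0.5, 0.5], [1])

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            loss([0.5], [2])


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic BPTT gradients vs central differences on every array."""
        model = make_model(units=3, d=4, V=12, merge_mode="concatenate", seed=10)
        seqs = [[1, 2, 3, 4], [5, 6], [7, 8, 9]]
        idx, mask = pad_batch(seqs)
        y = np.array([1, 0, 1])
        _, _, grads = model.forward_backward(idx, mask, y)
        params = model.param_dict()
        eps = 1e-6
        for name, arr in params.items():
            flat, g = arr.ravel(), grads[name].ravel()
            for j in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[j]
                flat[j] = old + eps
                lp, _, _ = model.forward_backward(idx, mask, y)
                flat[j] = old - eps
                lm, _, _ = model.forward_backward(idx, mask, y)
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert g[j] == pytest.approx(num, rel=1e-3, abs=1e-7), name

    def test_padding_row_gets_no_gradient(self):
        model = make_model(units=3, d=4, V=12, seed=11)
        idx, mask = pad_batch([[1, 2], [3, 4, 5]])
        _, _, grads = model.forward_backward(idx, mask, np.array([1, 0]))
        np.testing.assert_array_equal(grads["embedding"][0], 0.0)


def test_checkpoint_roundtrip_reproduces_predictions(tmp_path, rng):
    model = make_model(units=4, d=3, V=15, seed=12)
    seqs = [list(rng.integers(1, 16, size=7)) for _ in range(5)]
    before = model.predict_proba_batch(seqs)
    model.save(tmp_path / "ckpt", meta={"note": "test"})
    back = BiGRUClassifier.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(back.predict_proba_batch(seqs), before)
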