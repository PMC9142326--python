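"""The backpropagation scorer: transfer functions, forward pass against a
hand-unrolled oracle, gradient correctness, training behaviour and the
train/test protocol."""

import math

import numpy as np
import pytest

from voxscore import (EvaluationModel, evaluate, fit_normalization, forward,
                      init_model, mse, run_protocol, score_label,
                      score_to_target, train, transfer)
from voxscore.config import TrainingConfig
from voxscore.errors import (InsufficientDataError, ParameterError,
                             UnfittedModelError)
from voxscore.features import FeatureVector
from voxscore.network import loss_and_gradients


def _hand_forward(model, x):
    """Loop-and-scalar evaluation of the two-layer equations; the
    independent arithmetic oracle for the vectorized forward pass."""
    hidden = []
    for j in range(model.n_hidden):
        s = sum(model.w_ih[i, j] * x[i] for i in range(model.n_input))
        s -= model.theta_h[j]
        hidden.append(2.0 / (1.0 + math.exp(-2.0 * s)) - 1.0)
    outs = []
    for t in range(model.n_output):
        l = sum(model.w_ho[j, t] * hidden[j] for j in range(model.n_hidden))
        l -= model.gamma_o[t]
        outs.append(1.0 / (1.0 + math.exp(-l)))
    return np.array(outs), np.array(hidden)


class TestTransfer:
    def test_values_at_zero(self):
        assert transfer("tansig", 0.0) == 0.0
        assert transfer("logsig", 0.0) == 0.5

    def test_tansig_odd_symmetry(self):
        x = np.linspace(-5, 5, 11)
        assert np.allclose(transfer("tansig", -x), -transfer("tansig", x))

    def test_logsig_complement(self):
        x = np.linspace(-5, 5, 11)
        assert np.allclose(transfer("logsig", x) + transfer("logsig", -x), 1.0)

    def test_ranges(self):
        x = np.linspace(-50, 50, 101)
        assert np.all(np.abs(transfer("tansig", x)) <= 1.0)
        out = transfer("logsig", x)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            transfer("relu", 0.0)


class TestInitModel:
    def test_deterministic_per_seed(self):
        a, b = init_model(seed=5), init_model(seed=5)
        assert np.array_equal(a.w_ih, b.w_ih)
        assert np.array_equal(a.gamma_o, b.gamma_o)

    def test_unit_interval_bounds_respected(self):
        cfg = TrainingConfig(init_low=0.0, init_high=1.0)
        m = init_model(25, seed=1, config=cfg)
        for arr in (m.w_ih, m.theta_h, m.w_ho, m.gamma_o):
            assert np.all((arr >= 0.0) & (arr <= 1.0))

    def test_default_shapes_8_25_1(self):
        m = init_model(25, seed=0)
        assert m.w_ih.shape == (8, 25)
        assert m.theta_h.shape == (25,)
        assert m.w_ho.shape == (25, 1)
        assert m.gamma_o.shape == (1,)


class TestForward:
    def test_zero_parameters_give_half(self):
        m = EvaluationModel(w_ih=np.zeros((8, 4)), theta_h=np.zeros(4),
                            w_ho=np.zeros((4, 1)), gamma_o=np.zeros(1))
        out, _ = forward(m, np.full(8, 0.3))
        assert out[0] == 0.5

    def test_matches_hand_unrolled_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            m = EvaluationModel(
                w_ih=rng.uniform(-2, 2, (2, 2)), theta_h=rng.uniform(-1, 1, 2),
                w_ho=rng.uniform(-2, 2, (2, 1)), gamma_o=rng.uniform(-1, 1, 1))
            x = rng.uniform(0, 1, 2)
            out, hidden = forward(m, x)
            oracle_out, oracle_hidden = _hand_forward(m, x)
            assert np.allclose(out, oracle_out, atol=1e-12)
            assert np.allclose(hidden, oracle_hidden, atol=1e-12)

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(22)
        m = init_model(25, seed=3)
        out, _ = forward(m, rng.uniform(0, 1, (50, 8)))
        assert np.all((out > 0.0) & (out < 1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError):
            forward(init_model(4, seed=0), np.zeros(5))


class TestGradients:
    def test_analytic_matches_central_differences(self):
        rng = np.random.default_rng(23)
        model = init_model(25, seed=4)
        X = rng.uniform(0, 1, (12, 8))
        y = rng.uniform(0.1, 0.9, (12, 1))
        _, grads = loss_and_gradients(model, X, y)
        h = 1e-6
        for name in ("w_ih", "theta_h", "w_ho", "gamma_o"):
            arr = getattr(model, name)
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                up, _ = loss_and_gradients(model, X, y)
                arr[idx] = orig - h
                down, _ = loss_and_gradients(model, X, y)
                arr[idx] = orig
                fd[idx] = (up - down) / (2 * h)
            denom = np.abs(grads[name]) + np.abs(fd) + 1e-12
            assert np.max(np.abs(grads[name] - fd) / denom) < 1e-6


class TestTrain:
    def test_xor_style_separation(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0.1, 0.9, 0.9, 0.1])
        cfg = TrainingConfig(learning_rate=0.5, max_error=0.01,
                             max_iterations=20000, n_hidden=5, seed=0)
        model = init_model(5, seed=0, config=cfg, n_input=2)
        trained, history = train(model, X, y, cfg)
        out, _ = forward(trained, X)
        assert mse(out[:, 0], y) < 0.01

    def test_zero_learning_rate_is_noop(self):
        rng = np.random.default_rng(24)
        X, y = rng.uniform(0, 1, (6, 8)), rng.uniform(0.2, 0.8, 6)
        cfg = TrainingConfig(learning_rate=0.0, max_error=0.0, max_iterations=50)
        model = init_model(10, seed=1, config=cfg)
        trained, history = train(model, X, y, cfg)
        assert np.array_equal(trained.w_ih, model.w_ih)
        assert np.allclose(history, history[0])

    def test_descent_at_small_learning_rate(self, scored_corpus_features):
        _, features, scores = scored_corpus_features
        norm = fit_normalization(list(features.values()))
        from voxscore import apply_normalization
        ids = sorted(features)
        X = np.stack([apply_normalization(features[i], norm) for i in ids])
        y = np.array([score_to_target(scores[i]) for i in ids])
        cfg = TrainingConfig(learning_rate=0.05, max_error=0.0,
                             max_iterations=2000)
        model = init_model(25, seed=2, config=cfg)
        _, history = train(model, X, y, cfg)
        assert history[-1] < history[0]

    def test_targets_outside_open_interval_rejected(self):
        cfg = TrainingConfig()
        model = init_model(4, seed=0, n_input=2)
        with pytest.raises(ParameterError):
            train(model, np.zeros((2, 2)), np.array([0.0, 1.0]), cfg)

    def test_error_history_length_equals_epochs(self):
        rng = np.random.default_rng(25)
        X, y = rng.uniform(0, 1, (6, 8)), rng.uniform(0.2, 0.8, 6)
        cfg = TrainingConfig(max_error=0.0, max_iterations=17)
        _, history = train(init_model(5, seed=0, config=cfg), X, y, cfg)
        assert history.size == 17


class TestMse:
    def test_identical_is_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_example(self):
        assert mse([0.0, 1.0], [1.0, 0.0]) == 1.0

    def test_single_pair(self):
        assert mse([0.2], [0.5]) == pytest.approx(0.09)

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            mse([1.0], [1.0, 2.0])


class TestEvaluate:
    def _fitted_model(self, bias):
        v1 = FeatureVector(700, 2600, 220, 3, 1e-5, 1e-5, 2e-5, 10)
        v2 = FeatureVector(800, 2900, 330, 6, 2e-5, 3e-5, 4e-5, 40)
        m = EvaluationModel(w_ih=np.zeros((8, 2)), theta_h=np.zeros(2),
                            w_ho=np.zeros((2, 1)), gamma_o=np.array([-bias]))
        m.norm_params = fit_normalization([v1, v2])
        return m, v1

    def test_forced_output_09_is_good(self):
        bias = np.log(0.9 / 0.1)  # logsig(bias) = 0.9
        model, v = self._fitted_model(bias)
        record = evaluate(model, v, sample_id="a")
        assert record.objective_score == pytest.approx(9.0, abs=1e-9)
        assert record.label == "good"

    def test_forced_output_05_is_poor(self):
        model, v = self._fitted_model(0.0)
        record = evaluate(model, v, sample_id="b")
        assert record.objective_score == pytest.approx(5.0)
        assert record.label == "poor"

    def test_label_step_exactly_at_six(self):
        assert score_label(6.0) == "poor"
        assert score_label(6.0 + 1e-12) == "good"

    def test_unfitted_model_raises(self):
        m = init_model(4, seed=0)
        with pytest.raises(UnfittedModelError):
            evaluate(m, FeatureVector(700, 2600, 220, 3, 1e-5, 1e-5, 2e-5, 10))

    def test_deterministic(self):
        model, v = self._fitted_model(1.0)
        r1, r2 = evaluate(model, v), evaluate(model, v)
        assert r1.objective_score == r2.objective_score


class TestModelSerialization:
    def test_json_roundtrip_bit_exact(self):
        m = init_model(25, seed=9)
        v1 = FeatureVector(700, 2600, 220, 3, 1e-5, 1e-5, 2e-5, 10)
        v2 = FeatureVector(800, 2900, 330, 6, 2e-5, 3e-5, 4e-5, 40)
        m.norm_params = fit_normalization([v1, v2])
        back = EvaluationModel.from_json(m.to_json())
        assert np.array_equal(back.w_ih, m.w_ih)
        assert np.array_equal(back.theta_h, m.theta_h)
        assert np.array_equal(back.w_ho, m.w_ho)
        assert np.array_equal(back.norm_params.minimum, m.norm_params.minimum)


class TestRunProtocol:
    def test_split_sizes_22_samples(self, scored_corpus_features):
        _, features, scores = scored_corpus_features
        report = run_protocol(features, scores, seed=0)
        assert len(report.train_ids) == 12
        assert len(report.test_ids) == 10

    def test_reproducible_per_seed(self, scored_corpus_features):
        _, features, scores = scored_corpus_features
        a = run_protocol(features, scores, seed=4)
        b = run_protocol(features, scores, seed=4)
        assert a.train_ids == b.train_ids
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.error_history, b.error_history)
        assert all(x.objective_score == y.objective_score
                   for x, y in zip(a.records, b.records))

    def test_noiseless_deterministic_scores_reach_full_accuracy(self):
        # scores an exact smooth function of the features: the network can
        # recover the mapping and label every test sample correctly
        rng = np.random.default_rng(26)
        features, scores = {}, {}
        for i in range(22):
            jit = rng.uniform(1e-6, 1e-4)
            energy = rng.uniform(5, 50)
            f0 = rng.uniform(180, 350)
            fv = FeatureVector(700.0, 2600.0, f0, 3.0, jit, 1e-5, 2e-5, energy)
            sid = f"x{i:02d}"
            features[sid] = fv
            scores[sid] = 10.0 / (1.0 + np.exp(-(energy - 27.5) / 5.0))
        report = run_protocol(features, scores, seed=1)
        assert report.accuracy == 1.0

    def test_insufficient_class_counts_raise(self):
        features = {f"s{i}": FeatureVector(700, 2600, 220, 3, 1e-5, 1e-5,
                                           2e-5, 10 + i) for i in range(8)}
        scores = {k: 9.0 for k in features}  # no poor samples at all
        with pytest.raises(InsufficientDataError):
            run_protocol(features, scores, seed=0)
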