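"""Backpropagation scorer: an 8-h-1 multilayer perceptron trained by
full-batch gradient descent on mean squared error.

Forward pass (the Delta-rule network):

    hidden:  S_j = sum_i w_ij a_i - theta_j,   b_j = tansig(S_j)
    output:  L_t = sum_j v_jt b_j - gamma_t,   C_t = logsig(L_t)

with tansig(x) = 2/(1+exp(-2x)) - 1 and logsig(x) = 1/(1+exp(-x)).
The single output C in (0, 1) is scaled by 10 to a score on the 10-point
subjective scale; a score above 6 is labelled "good", otherwise "poor".

Training is plain gradient descent (no momentum, no adaptive rates) on
MSE between C and the subjective score / 10, stopping at a target error
or an epoch cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import TrainingConfig
from .errors import (DivergenceError, InsufficientDataError, ParameterError,
                     UnfittedModelError)
from .features import FeatureVector, NormalizationParams, apply_normalization

SCORE_SCALE = 10.0
GOOD_THRESHOLD = 6.0
# targets are kept strictly inside logsig's open range
TARGET_CLAMP = (0.05, 0.95)


def transfer(kind: str, x):
    """Evaluate a named transfer function elementwise.

    tansig maps to (-1, 1), logsig to (0, 1).
    """
    x = np.asarray(x, dtype=np.float64)
    if kind == "tansig":
        out = 2.0 / (1.0 + np.exp(-2.0 * x)) - 1.0
    elif kind == "logsig":
        out = 1.0 / (1.0 + np.exp(-x))
    else:
        raise ParameterError(f"unknown transfer function {kind!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class EvaluationModel:
    """Weights, thresholds and normalization state of the scorer.

    Shapes: w_ih (n_input, n_hidden), theta_h (n_hidden,),
    w_ho (n_hidden, n_output), gamma_o (n_output,).
    """

    w_ih: np.ndarray
    theta_h: np.ndarray
    w_ho: np.ndarray
    gamma_o: np.ndarray
    hidden_transfer: str = "tansig"
    output_transfer: str = "logsig"
    norm_params: NormalizationParams | None = None
    score_scale: float = SCORE_SCALE

    def __post_init__(self) -> None:
        n_in, n_hidden = self.w_ih.shape
        if self.theta_h.shape != (n_hidden,):
            raise ParameterError("theta_h shape mismatch")
        if self.w_ho.shape[0] != n_hidden:
            raise ParameterError("w_ho shape mismatch")
        if self.gamma_o.shape != (self.w_ho.shape[1],):
            raise ParameterError("gamma_o shape mismatch")
        for arr in (self.w_ih, self.theta_h, self.w_ho, self.gamma_o):
            if not np.all(np.isfinite(arr)):
                raise ParameterError("model parameters must be finite")

    @property
    def n_input(self) -> int:
        return self.w_ih.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    @property
    def n_output(self) -> int:
        return self.w_ho.shape[1]

    def to_json(self) -> str:
        doc = {
            "w_ih": self.w_ih.tolist(), "theta_h": self.theta_h.tolist(),
            "w_ho": self.w_ho.tolist(), "gamma_o": self.gamma_o.tolist(),
            "hidden_transfer": self.hidden_transfer,
            "output_transfer": self.output_transfer,
            "score_scale": self.score_scale,
            "norm_params": self.norm_params.to_dict() if self.norm_params else None,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationModel":
        doc = json.loads(text)
        norm = doc.get("norm_params")
        return cls(
            w_ih=np.asarray(doc["w_ih"], dtype=np.float64),
            theta_h=np.asarray(doc["theta_h"], dtype=np.float64),
            w_ho=np.asarray(doc["w_ho"], dtype=np.float64),
            gamma_o=np.asarray(doc["gamma_o"], dtype=np.float64),
            hidden_transfer=doc["hidden_transfer"],
            output_transfer=doc["output_transfer"],
            score_scale=doc["score_scale"],
            norm_params=NormalizationParams.from_dict(norm) if norm else None,
        )


@dataclass(frozen=True)
class ScoreRecord:
    """One sample's subjective and objective scores plus the good/poor
    label derived from the objective score."""

    sample_id: str
    objective_score: float
    subjective_score: float | None = None
    label: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if not 0.0 <= self.objective_score <= SCORE_SCALE:
            raise ParameterError("objective score must lie in [0, 10]")
        object.__setattr__(self, "label",
                           score_label(self.objective_score))


def score_label(score: float) -> str:
    """Good/poor cut on the 10-point scale: good iff score > 6."""
    return "good" if score > GOOD_THRESHOLD else "poor"


def init_model(n_hidden: int = 25, seed: int = 0,
               config: TrainingConfig | None = None,
               n_input: int = 8, n_output: int = 1) -> EvaluationModel:
    """Draw all weights and thresholds uniformly from the configured
    initialization interval (default [0, 1]); deterministic per seed."""
    if config is None:
        config = TrainingConfig(n_hidden=n_hidden, seed=seed)
    if n_hidden < 1:
        raise ParameterError("n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    low, high = config.init_low, config.init_high
    draw = lambda *shape: rng.uniform(low, high, size=shape)
    return EvaluationModel(w_ih=draw(n_input, n_hidden), theta_h=draw(n_hidden),
                           w_ho=draw(n_hidden, n_output), gamma_o=draw(n_output))


def forward(model: EvaluationModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass; returns (outputs, hidden activations).

    ``x`` may be a single vector (n_input,) or a batch (n, n_input).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    batch = np.atleast_2d(x)
    if batch.shape[1] != model.n_input:
        raise ParameterError(
            f"expected {model.n_input} inputs, got {batch.shape[1]}")
    hidden = transfer(model.hidden_transfer, batch @ model.w_ih - model.theta_h)
    out = transfer(model.output_transfer, hidden @ model.w_ho - model.gamma_o)
    if single:
        return out[0], hidden[0]
    return out, hidden


def mse(predicted, actual) -> float:
    """Mean squared error between two equal-length score sequences."""
    predicted = np.asarray(predicted, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if predicted.shape != actual.shape:
        raise ParameterError(
            f"shape mismatch {predicted.shape} vs {actual.shape}")
    if predicted.size == 0:
        raise InsufficientDataError("mse needs at least one value")
    return float(np.mean((predicted - actual) ** 2))


def loss_and_gradients(model: EvaluationModel, X: np.ndarray,
                       y: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """MSE loss and its analytic gradients w.r.t. all parameters.

    Derivatives use tansig'(s) = 1 - b^2 and logsig'(l) = c(1 - c);
    thresholds enter with a minus sign, hence their gradients are the
    negated delta sums.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64).reshape(X.shape[0], -1))
    n = X.shape[0]
    out, hidden = forward(model, X)
    err = out - y
    loss = float(np.mean(err ** 2))
    # dL/d(out) * logsig'  -> output-layer delta
    delta_o = (2.0 / err.size) * err * out * (1.0 - out)
    grad_w_ho = hidden.T @ delta_o
    grad_gamma = -delta_o.sum(axis=0)
    delta_h = (delta_o @ model.w_ho.T) * (1.0 - hidden ** 2)
    grad_w_ih = X.T @ delta_h
    grad_theta = -delta_h.sum(axis=0)
    return loss, {"w_ih": grad_w_ih, "theta_h": grad_theta,
                  "w_ho": grad_w_ho, "gamma_o": grad_gamma}


def train(model: EvaluationModel, X: np.ndarray, y: np.ndarray,
          config: TrainingConfig) -> tuple[EvaluationModel, np.ndarray]:
    """Full-batch gradient descent until MSE <= max_error or the epoch cap.

    Returns the trained model (the input model is not mutated) and the
    per-epoch error history (MSE evaluated before each update).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).reshape(X.shape[0], -1)
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ParameterError("X and y must have the same nonzero length")
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ParameterError("targets must lie strictly in (0, 1)")
    model = EvaluationModel(
        w_ih=model.w_ih.copy(), theta_h=model.theta_h.copy(),
        w_ho=model.w_ho.copy(), gamma_o=model.gamma_o.copy(),
        hidden_transfer=model.hidden_transfer,
        output_transfer=model.output_transfer,
        norm_params=model.norm_params, score_scale=model.score_scale)
    lr = config.learning_rate
    history = []
    for _ in range(config.max_iterations):
        loss, grads = loss_and_gradients(model, X, y)
        if not np.isfinite(loss):
            raise DivergenceError(
                "training diverged (non-finite loss); try a smaller learning rate")
        history.append(loss)
        if loss <= config.max_error:
            break
        model.w_ih -= lr * grads["w_ih"]
        model.theta_h -= lr * grads["theta_h"]
        model.w_ho -= lr * grads["w_ho"]
        model.gamma_o -= lr * grads["gamma_o"]
    return model, np.asarray(history)


def evaluate(model: EvaluationModel, features: FeatureVector,
             sample_id: str = "", subjective_score: float | None = None) -> ScoreRecord:
    """Score one recording: normalize, forward, scale to 10 points, label."""
    if model.norm_params is None:
        raise UnfittedModelError(
            "model has no normalization parameters; train it first")
    x = apply_normalization(features, model.norm_params)
    out, _ = forward(model, x)
    score = float(model.score_scale * out[0])
    return ScoreRecord(sample_id=sample_id, objective_score=score,
                       subjective_score=subjective_score)


@dataclass(frozen=True)
class ProtocolReport:
    """Outcome of one train/test evaluation run."""

    records: list[ScoreRecord]
    accuracy: float            # good/poor agreement on the test set, in [0, 1]
    final_mse: float           # training MSE at the last epoch (0-1 scale)
    error_history: np.ndarray
    train_ids: list[str]
    test_ids: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample_id": [r.sample_id for r in self.records],
             "subjective_score": [r.subjective_score for r in self.records],
             "objective_score": [r.objective_score for r in self.records],
             "label": [r.label for r in self.records]})


def score_to_target(score: float) -> float:
    """Map a 10-point subjective score to a network target in (0, 1)."""
    return float(np.clip(score / SCORE_SCALE, *TARGET_CLAMP))


def run_protocol(features: dict[str, FeatureVector], scores: dict[str, float],
                 n_train_good: int = 6, n_train_poor: int = 6,
                 seed: int = 0, config: TrainingConfig | None = None) -> ProtocolReport:
    """The train/test evaluation protocol.

    Randomly selects ``n_train_good`` good and ``n_train_poor`` poor
    samples (by their subjective labels) for training and scores the
    remaining samples with the trained network.  Accuracy is the fraction
    of test samples whose objective good/poor label agrees with the
    subjective one.
    """
    from .features import fit_normalization  # local to avoid cycle at import time

    if config is None:
        config = TrainingConfig(seed=seed)
    ids = sorted(set(features) & set(scores))
    missing = sorted(set(features) ^ set(scores))
    if missing:
        raise ParameterError(f"features/scores tables do not join on ids: {missing}")
    good_ids = [i for i in ids if score_label(scores[i]) == "good"]
    poor_ids = [i for i in ids if score_label(scores[i]) == "poor"]
    if len(good_ids) < n_train_good or len(poor_ids) < n_train_poor:
        raise InsufficientDataError(
            f"need >= {n_train_good} good and {n_train_poor} poor samples; "
            f"have {len(good_ids)} good, {len(poor_ids)} poor")
    rng = np.random.default_rng(seed)
    train_ids = sorted(list(rng.choice(good_ids, n_train_good, replace=False))
                       + list(rng.choice(poor_ids, n_train_poor, replace=False)))
    test_ids = [i for i in ids if i not in set(train_ids)]

    norm = fit_normalization([features[i] for i in train_ids])
    X = np.stack([apply_normalization(features[i], norm) for i in train_ids])
    y = np.array([score_to_target(scores[i]) for i in train_ids])
    model = init_model(config.n_hidden, seed=seed, config=config,
                       n_input=X.shape[1])
    model, history = train(model, X, y, config)
    model.norm_params = norm

    records = [evaluate(model, features[i], sample_id=i,
                        subjective_score=scores[i]) for i in test_ids]
    agree = [r.label == score_label(r.subjective_score) for r in records]
    accuracy = float(np.mean(agree)) if agree else float("nan")
    return ProtocolReport(records=records, accuracy=accuracy,
                          final_mse=float(history[-1]), error_history=history,
                          train_ids=train_ids, test_ids=test_ids)
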