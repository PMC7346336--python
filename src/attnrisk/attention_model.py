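"""Attention-gated neural network for interpretable binary prediction.

The model computes a per-patient attention vector over the m input features,

    alpha = softmax(W x + b),

gates the input element-wise, g = alpha * x, and feeds g through a
fully-connected MLP with ReLU hidden layers and a single sigmoid output unit.
Because each alpha lies on the probability simplex, its entries can be read
directly as the relative contribution of each feature to that patient's
prediction. Training minimizes mean binary cross-entropy plus an L2 penalty
lambda * ||Theta||^2 over all weight matrices (attention W and MLP layer
weights; bias vectors are not penalized).

The same machinery with ``use_attention=False`` is the plain-MLP baseline:
with zero attention parameters the gated model is numerically identical to a
plain MLP applied to x/m (uniform attention), a property the tests verify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    EPS_CLIP,
    Adam,
    binary_cross_entropy,
    glorot_uniform,
    relu,
    sigmoid,
    softmax_rows,
    stratified_validation_split,
)
from .data_io import PatientCohort


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the attention model (and the plain MLP baseline).

    Defaults follow the study settings where stated (learning rate 0.001,
    L2 coefficient 0.001, decision threshold 0.5, one to five hidden layers);
    the remainder (width 64, ReLU, Adam, batch 32, max 300 epochs, early
    stopping with patience 20 on a 10% validation split) are standard choices
    for small tabular networks.
    """

    n_hidden_layers: int = 1
    hidden_width: int = 64
    learning_rate: float = 0.001
    lambda_: float = 0.001
    threshold: float = 0.5
    epochs: int = 300
    batch_size: int = 32
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_hidden_layers < 1:
            raise ModelError("need at least one hidden layer")
        if not (0 < self.threshold < 1):
            raise ModelError("threshold must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be positive")
        if self.lambda_ < 0:
            raise ModelError("lambda_ must be nonnegative")


@dataclass
class AttentionParams:
    """Attention-layer parameters: logits = W x + b with W m x m, b length m."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ModelError("attention W must be square (m x m)")
        if self.b.shape != (self.W.shape[0],):
            raise ModelError("attention b must have length m")


@dataclass
class MLPParams:
    """Ordered (weight, bias) pairs for hidden layers plus the output unit."""

    layers: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for i, (W, b) in enumerate(self.layers):
            if b.shape != (W.shape[1],):
                raise ModelError(f"layer {i} bias does not match weight columns")
            if i > 0 and W.shape[0] != self.layers[i - 1][0].shape[1]:
                raise ModelError(f"layer {i} input does not chain with layer {i-1}")
        if self.layers[-1][0].shape[1] != 1:
            raise ModelError("final layer must output a single unit")


@dataclass
class AttentionMatrix:
    """Per-patient attention vectors; each row is a point on the simplex."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 2:
            raise ModelError("alpha must be an n x m matrix")
        # mathematically entries lie strictly in (0, 1); in floating point a
        # saturated softmax can round an entry up to exactly 1.0
        if not ((self.alpha > 0) & (self.alpha <= 1)).all():
            raise ModelError("attention entries must lie in (0, 1]")
        if not np.allclose(self.alpha.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("attention rows must sum to one")


@dataclass
class Prediction:
    """Predicted probabilities and thresholded labels (1 iff prob > threshold)."""

    probs: np.ndarray
    labels: np.ndarray
    threshold: float


def compute_attention(x: np.ndarray, params: AttentionParams) -> np.ndarray:
    """softmax(W x + b) for one feature vector; numerically stabilized."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ModelError("non-finite input")
    if x.shape != (params.W.shape[1],):
        raise ModelError(
            f"input length {x.shape} does not match attention dimension {params.W.shape}"
        )
    return softmax_rows((params.W @ x + params.b)[None, :])[0]


def gate_input(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Element-wise gating g = alpha * x."""
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ModelError("x and alpha must have equal length")
    return alpha * x


class AttentionClassifier:
    """The trainable model: attention gate (optional) + ReLU MLP + sigmoid.

    Parameters live in a flat dict: ``attn_W``/``attn_b`` (when attention is
    on) and ``W{i}``/``b{i}`` for the MLP layers, ``i = 0 .. n_hidden`` with
    the last layer the single output unit.
    """

    def __init__(self, m: int, config: ModelConfig, use_attention: bool = True):
        config.validate()
        self.m = m
        self.config = config
        self.use_attention = use_attention
        self.params: dict[str, np.ndarray] = {}
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self._init_params()

    # -- parameters ---------------------------------------------------------
    def _layer_dims(self) -> list[tuple[int, int]]:
        dims = []
        prev = self.m
        for _ in range(self.config.n_hidden_layers):
            dims.append((prev, self.config.hidden_width))
            prev = self.config.hidden_width
        dims.append((prev, 1))
        return dims

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        p: dict[str, np.ndarray] = {}
        if self.use_attention:
            p["attn_W"] = glorot_uniform(rng, self.m, self.m).T  # (m, m), logits = X @ W.T
            p["attn_b"] = np.zeros(self.m)
        for i, (fan_in, fan_out) in enumerate(self._layer_dims()):
            p[f"W{i}"] = glorot_uniform(rng, fan_in, fan_out)
            p[f"b{i}"] = np.zeros(fan_out)
        self.params = p

    @property
    def attention_params(self) -> AttentionParams | None:
        if not self.use_attention:
            return None
        return AttentionParams(self.params["attn_W"], self.params["attn_b"])

    @property
    def mlp_params(self) -> MLPParams:
        n_layers = self.config.n_hidden_layers + 1
        return MLPParams(
            [(self.params[f"W{i}"], self.params[f"b{i}"]) for i in range(n_layers)]
        )

    def set_attention_to_zero(self) -> None:
        """Zero the attention parameters (uniform attention on every input)."""
        if self.use_attention:
            self.params["attn_W"][:] = 0.0
            self.params["attn_b"][:] = 0.0

    # -- forward / loss / gradients -----------------------------------------
    def _forward_full(self, X: np.ndarray):
        """Forward pass keeping intermediates for backprop."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.m:
            raise ModelError(f"X must be n x {self.m}")
        if not np.isfinite(X).all():
            raise ModelError("non-finite input")
        cache: dict[str, object] = {"X": X}
        if self.use_attention:
            logits = X @ self.params["attn_W"].T + self.params["attn_b"]
            alpha = softmax_rows(logits)
            h = alpha * X
            cache["alpha"] = alpha
        else:
            alpha = None
            h = X
        activations = [h]
        preacts = []
        n_layers = self.config.n_hidden_layers + 1
        for i in range(n_layers):
            s = activations[-1] @ self.params[f"W{i}"] + self.params[f"b{i}"]
            preacts.append(s)
            activations.append(relu(s) if i < n_layers - 1 else s)
        probs = sigmoid(preacts[-1][:, 0])
        cache["activations"] = activations
        cache["preacts"] = preacts
        cache["probs"] = probs
        return probs, alpha, cache

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, AttentionMatrix | None]:
        """Predicted probabilities and the attention matrix used to get them."""
        probs, alpha, _ = self._forward_full(X)
        return probs, (AttentionMatrix(alpha) if alpha is not None else None)

    def _penalty(self, lam: float) -> float:
        # Theta = attention parameters (W and b) + MLP weight matrices.
        # MLP biases are excluded (standard weight-decay practice); the
        # attention bias IS penalized because it directly parametrizes the
        # attention distribution — under a dominant penalty the attention
        # collapses to uniform, which an unpenalized bias would not guarantee.
        return lam * sum(
            float(np.sum(v * v)) for k, v in self.params.items() if not k.startswith("b")
        )

    def compute_loss(
        self, X: np.ndarray, Y: np.ndarray, lambda_: float | None = None
    ) -> float:
        """Mean cross-entropy (probabilities clipped by 1e-7) + L2 weight penalty."""
        Y = np.asarray(Y)
        if not np.isin(Y, (0, 1)).all():
            raise ModelError("labels must be binary")
        lam = self.config.lambda_ if lambda_ is None else lambda_
        probs, _, _ = self._forward_full(X)
        return binary_cross_entropy(probs, Y) + self._penalty(lam)

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, lambda_: float | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Analytic gradients of the penalized loss w.r.t. every parameter."""
        Y = np.asarray(Y, dtype=float)
        lam = self.config.lambda_ if lambda_ is None else lambda_
        probs, alpha, cache = self._forward_full(X)
        n = len(Y)
        loss = binary_cross_entropy(probs, Y) + self._penalty(lam)

        p = cache["probs"]
        pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
        active = ((p > EPS_CLIP) & (p < 1.0 - EPS_CLIP)).astype(float)
        dL_dp = (pc - Y) / (pc * (1.0 - pc)) / n * active
        dz = dL_dp * p * (1.0 - p)  # gradient through the output sigmoid

        grads: dict[str, np.ndarray] = {}
        activations = cache["activations"]
        preacts = cache["preacts"]
        n_layers = self.config.n_hidden_layers + 1
        delta = dz[:, None]
        for i in range(n_layers - 1, -1, -1):
            W = self.params[f"W{i}"]
            grads[f"W{i}"] = activations[i].T @ delta + 2.0 * lam * W
            grads[f"b{i}"] = delta.sum(axis=0)
            delta = delta @ W.T
            if i > 0:
                delta = delta * (preacts[i - 1] > 0)
        if self.use_attention:
            X_arr = cache["X"]
            d_g = delta  # gradient at the gated input g = alpha * x
            d_alpha = d_g * X_arr
            # softmax Jacobian: d_logits = alpha * (d_alpha - <d_alpha, alpha>)
            inner = (d_alpha * alpha).sum(axis=1, keepdims=True)
            d_logits = alpha * (d_alpha - inner)
            grads["attn_W"] = d_logits.T @ X_arr + 2.0 * lam * self.params["attn_W"]
            grads["attn_b"] = d_logits.sum(axis=0) + 2.0 * lam * self.params["attn_b"]
        return loss, grads

    # -- training -----------------------------------------------------------
    def fit(self, train: PatientCohort) -> "AttentionClassifier":
        """Mini-batch Adam on the penalized cross-entropy, seeded and deterministic.

        When ``patience > 0`` a stratified validation split of ``val_fraction``
        is carved out of the training data; the unpenalized validation
        cross-entropy drives early stopping and the best parameters are
        restored at the end.
        """
        cfg = self.config
        if len(np.unique(train.Y)) < 2:
            raise ModelError("training data must contain both classes")
        if train.m != self.m:
            raise ModelError("training feature count does not match model")
        rng = np.random.default_rng(cfg.seed + 1)
        X, Y = train.X, train.Y.astype(float)
        use_val = cfg.patience > 0 and cfg.val_fraction > 0 and train.n >= 20
        if use_val:
            tr_idx, val_idx = stratified_validation_split(train.Y, cfg.val_fraction, rng)
            if len(val_idx) == 0 or len(np.unique(train.Y[tr_idx])) < 2:
                use_val = False
        if use_val:
            X_tr, Y_tr = X[tr_idx], Y[tr_idx]
            X_val, Y_val = X[val_idx], Y[val_idx]
        else:
            X_tr, Y_tr = X, Y

        opt = Adam(self.params, lr=cfg.learning_rate)
        best_val = np.inf
        best_params = None
        stale = 0
        n_tr = len(Y_tr)
        for _ in range(cfg.epochs):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss, grads = self.loss_and_grads(X_tr[batch], Y_tr[batch])
                if not np.isfinite(loss):
                    raise ModelError("non-finite training loss; aborting fit")
                opt.step(self.params, grads)
            epoch_loss = self.compute_loss(X_tr, Y_tr)
            self.history["train_loss"].append(epoch_loss)
            if use_val:
                val_probs, _, _ = self._forward_full(X_val)
                val_loss = binary_cross_entropy(val_probs, Y_val)
                self.history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_params = {k: v.copy() for k, v in self.params.items()}
                    stale = 0
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
        if use_val and best_params is not None:
            self.params = best_params
        return self

    def predict(self, X: np.ndarray, threshold: float | None = None) -> Prediction:
        """Threshold probabilities into labels: 1 iff prob strictly > threshold."""
        thr = self.config.threshold if threshold is None else threshold
        if not (0 < thr < 1):
            raise ModelError("threshold must be in (0, 1)")
        probs, _ = self.forward(X)
        return Prediction(probs, (probs > thr).astype(int), thr)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize config + parameters to a single JSON file.

        Floats round-trip exactly (json preserves doubles via repr), so a
        reloaded model reproduces forward outputs bit-for-bit.
        """
        payload = {
            "format": "attnrisk-model-v1",
            "use_attention": self.use_attention,
            "m": self.m,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AttentionClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "attnrisk-model-v1":
            raise ModelError("unrecognized model file")
        config = ModelConfig(**payload["config"])
        model = cls(payload["m"], config, use_attention=payload["use_attention"])
        model.params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return model


def fit_attention_model(
    train: PatientCohort, config: ModelConfig | None = None
) -> AttentionClassifier:
    """Train the attention-gated classifier on a cohort."""
    config = config or ModelConfig()
    model = AttentionClassifier(train.m, config, use_attention=True)
    return model.fit(train)
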