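"""Comparison models: logistic regression, plain MLP, stacked denoising autoencoder.

All three consume a :class:`~attnrisk.data_io.PatientCohort` and emit the
same :class:`~attnrisk.attention_model.Prediction` contract as the attention
model, so the evaluation harness is model-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from ._nn import Adam, binary_cross_entropy, glorot_uniform, relu, sigmoid
from .attention_model import AttentionClassifier, ModelConfig, ModelError, Prediction
from .data_io import PatientCohort


@dataclass
class LogisticModel:
    """Fitted logistic regression; coefficients on the scale of the input features."""

    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(X @ self.coefficients + self.intercept)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> Prediction:
        probs = self.predict_proba(X)
        return Prediction(probs, (probs > threshold).astype(int), threshold)


def fit_logistic(train: PatientCohort, l2: float = 1e-4) -> LogisticModel:
    """Penalized Bernoulli MLE: minimize (1/n)·NLL + l2·||w||² (intercept unpenalized).

    ``l2=0`` gives the pure maximum-likelihood fit; with perfectly separable
    data and no penalty the optimum is at infinity, which is reported as a
    warning with the diverging coefficient norm.
    """
    if l2 < 0:
        raise ValueError("l2 must be nonnegative")
    if len(np.unique(train.Y)) < 2:
        raise ValueError("both classes must be present")
    if l2 == 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000, tol=1e-10)
    else:
        # sklearn minimizes NLL + (1/(2C))·||w||²; match (1/n)·NLL + l2·||w||²
        C = 1.0 / (2.0 * train.n * l2)
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(train.X, train.Y)
    coef = clf.coef_[0].astype(float)
    norm = float(np.linalg.norm(coef))
    if l2 == 0 and norm > 15:
        warnings.warn(
            f"possible perfect separation: coefficient norm {norm:.1f} is diverging",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticModel(coef, float(clf.intercept_[0]), list(train.feature_names))


def fit_plain_mlp(
    train: PatientCohort, config: ModelConfig | None = None
) -> AttentionClassifier:
    """Plain MLP baseline: identical training engine, no attention gate."""
    config = config or ModelConfig()
    model = AttentionClassifier(train.m, config, use_attention=False)
    return model.fit(train)


@dataclass
class SDAEConfig:
    """Stacked denoising autoencoder settings.

    Two encoding/decoding layers by default; masking corruption (random cells
    zeroed) at rate 0.2 and squared-error reconstruction during greedy
    layerwise pretraining, then a sigmoid head fine-tuned end-to-end with
    cross-entropy. Both phases use Adam at the study's 0.001 learning rate.
    """

    n_coder_layers: int = 2
    layer_widths: Sequence[int] = (64, 32)
    corruption_rate: float = 0.2
    pretrain_epochs: int = 100
    finetune_epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_coder_layers < 1:
            raise ModelError("need at least one coder layer")
        if len(self.layer_widths) != self.n_coder_layers:
            raise ModelError("layer_widths must have one width per coder layer")
        if not (0 <= self.corruption_rate < 1):
            raise ModelError("corruption_rate must be in [0, 1)")


class SDAEClassifier:
    """Denoising-autoencoder pretraining followed by supervised fine-tuning.

    Each coder layer is a ReLU encoder with a linear decoder trained to
    reconstruct its clean input from a masking-corrupted copy. After
    pretraining, the decoder stack is discarded and a sigmoid classification
    head on top of the encoder is fine-tuned end-to-end.
    """

    def __init__(self, m: int, config: SDAEConfig):
        config.validate()
        self.m = m
        self.config = config
        self.encoders: list[tuple[np.ndarray, np.ndarray]] = []
        self.head: tuple[np.ndarray, np.ndarray] | None = None
        self.pretrain_history: list[list[float]] = []

    # -- pretraining --------------------------------------------------------
    def _pretrain_layer(
        self,
        H: np.ndarray,
        width: int,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
        """Train one denoising autoencoder layer; return encoder params and codes."""
        cfg = self.config
        n, d = H.shape
        params = {
            "We": glorot_uniform(rng, d, width),
            "be": np.zeros(width),
            "Wd": glorot_uniform(rng, width, d),
            "bd": np.zeros(d),
        }
        opt = Adam(params, lr=cfg.learning_rate)
        history: list[float] = []
        for _ in range(cfg.pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = H[order[start : start + cfg.batch_size]]
                corrupted = batch
                if cfg.corruption_rate > 0:
                    mask = rng.random(batch.shape) >= cfg.corruption_rate
                    corrupted = batch * mask
                s = corrupted @ params["We"] + params["be"]
                code = relu(s)
                recon = code @ params["Wd"] + params["bd"]
                err = recon - batch  # reconstruct the CLEAN input
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise ModelError("non-finite pretraining loss")
                B = len(batch)
                d_recon = 2.0 * err / (B * batch.shape[1])
                grads = {
                    "Wd": code.T @ d_recon,
                    "bd": d_recon.sum(axis=0),
                }
                d_code = d_recon @ params["Wd"].T * (s > 0)
                grads["We"] = corrupted.T @ d_code
                grads["be"] = d_code.sum(axis=0)
                opt.step(params, grads)
            s_full = H @ params["We"] + params["be"]
            recon_full = relu(s_full) @ params["Wd"] + params["bd"]
            history.append(float(np.mean((recon_full - H) ** 2)))
        codes = relu(H @ params["We"] + params["be"])
        return params["We"], params["be"], codes, history

    def reconstruction_error(self, X: np.ndarray, layer: int = 0) -> float:
        """Mean squared pretraining reconstruction error recorded for a layer."""
        return self.pretrain_history[layer][-1]

    # -- training -----------------------------------------------------------
    def fit(self, train: PatientCohort) -> "SDAEClassifier":
        cfg = self.config
        if len(np.unique(train.Y)) < 2:
            raise ModelError("training data must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        H = train.X
        self.encoders = []
        self.pretrain_history = []
        for width in cfg.layer_widths:
            We, be, H, hist = self._pretrain_layer(H, width, rng)
            self.encoders.append((We, be))
            self.pretrain_history.append(hist)
        # supervised fine-tuning of encoder stack + sigmoid head
        params: dict[str, np.ndarray] = {}
        for i, (We, be) in enumerate(self.encoders):
            params[f"W{i}"] = We.copy()
            params[f"b{i}"] = be.copy()
        top = cfg.layer_widths[-1]
        params["Wh"] = glorot_uniform(rng, top, 1)
        params["bh"] = np.zeros(1)
        opt = Adam(params, lr=cfg.learning_rate)
        X, Y = train.X, train.Y.astype(float)
        n = len(Y)
        L = cfg.n_coder_layers
        for _ in range(cfg.finetune_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], Y[idx]
                acts, pres = [xb], []
                for i in range(L):
                    s = acts[-1] @ params[f"W{i}"] + params[f"b{i}"]
                    pres.append(s)
                    acts.append(relu(s))
                z = acts[-1] @ params["Wh"] + params["bh"]
                p = sigmoid(z[:, 0])
                loss = binary_cross_entropy(p, yb)
                if not np.isfinite(loss):
                    raise ModelError("non-finite fine-tuning loss")
                dz = ((p - yb) / len(yb))[:, None]
                grads = {"Wh": acts[-1].T @ dz, "bh": dz.sum(axis=0)}
                delta = dz @ params["Wh"].T
                for i in range(L - 1, -1, -1):
                    delta = delta * (pres[i] > 0)
                    grads[f"W{i}"] = acts[i].T @ delta
                    grads[f"b{i}"] = delta.sum(axis=0)
                    delta = delta @ params[f"W{i}"].T
                opt.step(params, grads)
        self.encoders = [(params[f"W{i}"], params[f"b{i}"]) for i in range(L)]
        self.head = (params["Wh"], params["bh"])
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise ModelError("model is not fitted")
        H = np.asarray(X, dtype=float)
        for We, be in self.encoders:
            H = relu(H @ We + be)
        Wh, bh = self.head
        return sigmoid((H @ Wh + bh)[:, 0])

    def predict(self, X: np.ndarray, threshold: float | None = None) -> Prediction:
        thr = self.config.threshold if threshold is None else threshold
        probs = self.predict_proba(X)
        return Prediction(probs, (probs > thr).astype(int), thr)


def fit_sdae(train: PatientCohort, config: SDAEConfig | None = None) -> SDAEClassifier:
    """Greedy layerwise pretraining then end-to-end fine-tuning; seeded."""
    config = config or SDAEConfig()
    model = SDAEClassifier(train.m, config)
    return model.fit(train)
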