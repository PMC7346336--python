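"""Attention-based interpretation: per-patient and global feature rankings.

Attention weights are nonnegative and directionless — they say how much a
feature contributed, not in which direction. Rankings here are therefore
magnitude-only; pair them with signed logistic-regression coefficients when
direction matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .attention_model import AttentionClassifier, AttentionMatrix
from .baselines import LogisticModel


@dataclass
class FeatureRanking:
    """Ordered (feature_name, score) pairs; scores descending, ties stable.

    ``scope`` is "per-patient" (scores are attention weights) or "global"
    (scores are top-k occurrence counts across patients). ``payload`` carries
    extra per-entry values (e.g. signed LR coefficients).
    """

    scope: str
    entries: list[tuple[str, float]]
    payload: dict[str, list[float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["feature", "score"])
        if self.payload:
            for k, v in self.payload.items():
                df[k] = v
        return df


def extract_attention(model: AttentionClassifier, X: np.ndarray) -> AttentionMatrix:
    """The per-patient attention vectors used in the forward pass on X."""
    if not model.use_attention:
        raise ValueError("model has no attention layer")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.m:
        raise ValueError(f"X must be n x {model.m}")
    _, alpha = model.forward(X)
    return alpha


def _stable_descending_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on negated scores keeps original feature order among ties
    return np.argsort(-scores, kind="stable")


def rank_patient_features(
    alpha_row: np.ndarray,
    feature_names: Sequence[str],
    k: int,
    min_weight: float | None = None,
) -> FeatureRanking:
    """Top-k features of one patient by attention weight, descending.

    When ``min_weight`` is given, only entries with weight strictly above it
    are kept. Ties break by original feature order.
    """
    alpha_row = np.asarray(alpha_row, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(alpha_row):
        raise ValueError("k exceeds the number of features")
    order = _stable_descending_order(alpha_row)[:k]
    entries = [(feature_names[j], float(alpha_row[j])) for j in order]
    if min_weight is not None:
        entries = [(f, w) for f, w in entries if w > min_weight]
    return FeatureRanking("per-patient", entries)


def global_frequency_ranking(
    alpha: AttentionMatrix,
    feature_names: Sequence[str],
    k: int = 10,
    top: int = 10,
) -> FeatureRanking:
    """Count, per feature, in how many patients' top-k it appears.

    Each patient contributes exactly k occurrences, so counts over ALL
    features sum to n·k. The ``top`` most frequent are returned.
    """
    A = alpha.alpha
    n, m = A.shape
    if n == 0:
        raise ValueError("empty attention matrix")
    if k > m:
        raise ValueError("k exceeds the number of features")
    counts = np.zeros(m, dtype=int)
    for row in A:
        counts[_stable_descending_order(row)[:k]] += 1
    order = _stable_descending_order(counts.astype(float))[:top]
    entries = [(feature_names[j], float(counts[j])) for j in order]
    return FeatureRanking("global", entries)


def lr_coefficient_ranking(model: LogisticModel, top: int = 10) -> FeatureRanking:
    """Features ranked by |coefficient| of a fitted logistic regression.

    Signed coefficients are retained in the payload so direction is not lost.
    """
    coefs = np.asarray(model.coefficients, dtype=float)
    order = _stable_descending_order(np.abs(coefs))[:top]
    entries = [(model.feature_names[j], float(abs(coefs[j]))) for j in order]
    payload = {"coefficient": [float(coefs[j]) for j in order]}
    return FeatureRanking("global", entries, payload)


def heatmap_matrix(
    alpha: AttentionMatrix,
    feature_names: Sequence[str] | None = None,
    n_sample: int | None = 50,
    seed: int = 0,
    log_base: float | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Log-transformed attention weights for a heat-map display.

    Natural log by default (``log_base`` switches); rows optionally a seeded
    random subset of patients (50 by default, or all rows when n < 50 or
    ``n_sample`` is None). Returns (matrix, row_labels, col_labels).
    """
    A = alpha.alpha
    n, m = A.shape
    if n_sample is not None and n_sample > n:
        n_sample = None
    if n_sample is None:
        rows = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(n, size=n_sample, replace=False))
    mat = np.log(A[rows])
    if log_base is not None:
        mat = mat / np.log(log_base)
    row_labels = [f"patient_{i}" for i in rows]
    col_labels = (
        list(feature_names) if feature_names is not None else [f"f{j+1}" for j in range(m)]
    )
    return mat, row_labels, col_labels


def plot_heatmap(mat: np.ndarray, row_labels, col_labels, path: str) -> None:
    """Render the log-attention heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="log attention weight")
    ax.set_xlabel("feature")
    ax.set_ylabel("patient")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def explanation_sheet(
    model: AttentionClassifier,
    X: np.ndarray,
    feature_names: Sequence[str],
    patient_index: int,
    k: int = 10,
) -> dict:
    """Per-patient explanation: prediction plus top-k attention table (JSON-able)."""
    pred = model.predict(X)
    alpha = extract_attention(model, X)
    ranking = rank_patient_features(alpha.alpha[patient_index], feature_names, k)
    return {
        "patient_index": int(patient_index),
        "probability": float(pred.probs[patient_index]),
        "predicted_label": int(pred.labels[patient_index]),
        "top_features": [{"feature": f, "attention": w} for f, w in ranking.entries],
    }
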