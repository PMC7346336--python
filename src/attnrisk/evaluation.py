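"""Experimental protocol: repeated stratified holdout with cross-validated tuning.

Per repetition r (seed = base_seed + r): a stratified 80/20 split is drawn,
features are z-scored with training-split statistics, each model tunes its
depth grid by mean five-fold CV AUC on the 80%, is refit on the full 80%,
and is scored on the untouched 20%. Metrics (accuracy, precision, recall,
F1, AUC) are summarized mean ± std over repetitions; paired t-tests compare
every model pair on the pooled per-patient predicted test labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .attention_model import AttentionClassifier, ModelConfig
from .baselines import SDAEClassifier, SDAEConfig, fit_logistic, fit_plain_mlp
from .data_io import PatientCohort, split_holdout, standardize_features

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class ProtocolConfig:
    n_repeats: int = 10
    n_folds: int = 5
    train_fraction: float = 0.8
    hidden_layer_grid: Sequence[int] = (1, 2, 3, 4, 5)
    base_seed: int = 0
    standardize: bool = True
    ttest_mode: str = "pooled"  # or "per_repetition"

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.ttest_mode not in ("pooled", "per_repetition"):
            raise ValueError("ttest_mode must be 'pooled' or 'per_repetition'")


@dataclass
class ModelSpec:
    """A model entry for the protocol.

    ``fit(train, depth, seed)`` returns a fitted object; ``score(fitted,
    cohort)`` returns (probabilities, labels) on a cohort. ``grid`` is the
    depth grid tuned by CV (None or a single value skips tuning).
    """

    name: str
    fit: Callable[[PatientCohort, int | None, int], Any]
    score: Callable[[Any, PatientCohort], tuple[np.ndarray, np.ndarray]]
    grid: Sequence[int] | None = None


@dataclass
class TTestResult:
    model_pair: tuple[str, str]
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


@dataclass
class MetricsReport:
    """Per-model per-repetition metric values plus mean ± std summaries."""

    per_repetition: dict[str, list[dict[str, float]]]
    chosen_depths: dict[str, list[int | None]]

    @property
    def model_names(self) -> list[str]:
        return list(self.per_repetition)

    def summary(self) -> dict[str, dict[str, tuple[float, float]]]:
        out: dict[str, dict[str, tuple[float, float]]] = {}
        for name, rows in self.per_repetition.items():
            out[name] = {}
            for metric in METRIC_NAMES:
                vals = np.array([r[metric] for r in rows])
                out[name][metric] = (float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, per_rep in self.per_repetition.items():
            for r, metrics in enumerate(per_rep):
                rows.append({"model": name, "repetition": r, **metrics})
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, metrics in self.summary().items():
            row: dict[str, object] = {"model": name}
            for metric, (mean, std) in metrics.items():
                row[metric] = f"{mean:.3f} ± {std:.3f}"
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics


def compute_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Area under the ROC curve as Mann–Whitney concordance, ties count 1/2.

    Computed via the rank-sum identity AUC = (R1 − n1(n1+1)/2) / (n1·n0)
    with midranks for ties, which agrees bit-for-bit with brute-force
    enumeration over all (positive, negative) pairs.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    if len(y_true) != len(y_score):
        raise ValueError("length mismatch")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: only one class present")
    ranks = stats.rankdata(y_score)
    n1 = int(np.sum(y_true == 1))
    n0 = len(y_true) - n1
    r1 = float(np.sum(ranks[np.asarray(y_true) == 1]))
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and AUC for binary predictions.

    Precision (and hence F1) with zero predicted positives is defined as 0
    with a warning rather than an error.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValueError("length mismatch among y_true, y_pred, y_score")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    accuracy = (tp + tn) / len(y_true)
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": compute_auc(y_true, y_score),
    }


def paired_t_test(pred_a: np.ndarray, pred_b: np.ndarray, names: tuple[str, str] = ("a", "b")) -> TTestResult:
    """Paired-samples t-test on per-item differences d = pred_a − pred_b.

    t = mean(d) / (sd(d)/√n) with sample sd (n−1 denominator); two-sided p
    from Student t with n−1 df. Conventions: d identically zero gives t=0,
    p=1; constant nonzero d (sd=0) gives infinite t, p=0, flagged degenerate.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pred_a and pred_b must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.all(d == 0):
        return TTestResult(names, 0.0, 1.0, n)
    sd = d.std(ddof=1)
    if sd == 0:
        t = np.inf if d.mean() > 0 else -np.inf
        return TTestResult(names, float(t), 0.0, n, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(names, float(t), float(p), n)


def mcnemar_test(
    pred_a: np.ndarray, pred_b: np.ndarray, y_true: np.ndarray
) -> tuple[float, float]:
    """McNemar's exact test on discordant correctness — the textbook-standard
    alternative to a t-test on paired binary predictions."""
    correct_a = np.asarray(pred_a) == np.asarray(y_true)
    correct_b = np.asarray(pred_b) == np.asarray(y_true)
    table = np.array(
        [
            [np.sum(correct_a & correct_b), np.sum(correct_a & ~correct_b)],
            [np.sum(~correct_a & correct_b), np.sum(~correct_a & ~correct_b)],
        ]
    )
    res = _sm_mcnemar(table, exact=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model spec builders


def attention_spec(config: ModelConfig | None = None, grid: Sequence[int] | None = None) -> ModelSpec:
    base = config or ModelConfig()

    def _fit(train: PatientCohort, depth: int | None, seed: int):
        cfg = ModelConfig(**{**base.__dict__, "seed": seed})
        if depth is not None:
            cfg.n_hidden_layers = depth
        model = AttentionClassifier(train.m, cfg, use_attention=True)
        return model.fit(train)

    def _score(model: AttentionClassifier, cohort: PatientCohort):
        pred = model.predict(cohort.X)
        return pred.probs, pred.labels

    return ModelSpec("MLP_attention", _fit, _score, grid)


def mlp_spec(config: ModelConfig | None = None, grid: Sequence[int] | None = None) -> ModelSpec:
    base = config or ModelConfig()

    def _fit(train: PatientCohort, depth: int | None, seed: int):
        cfg = ModelConfig(**{**base.__dict__, "seed": seed})
        if depth is not None:
            cfg.n_hidden_layers = depth
        return fit_plain_mlp(train, cfg)

    def _score(model: AttentionClassifier, cohort: PatientCohort):
        pred = model.predict(cohort.X)
        return pred.probs, pred.labels

    return ModelSpec("MLP", _fit, _score, grid)


def lr_spec(l2: float = 1e-4) -> ModelSpec:
    def _fit(train: PatientCohort, depth: int | None, seed: int):
        return fit_logistic(train, l2=l2)

    def _score(model, cohort: PatientCohort):
        pred = model.predict(cohort.X)
        return pred.probs, pred.labels

    return ModelSpec("LR", _fit, _score, None)


def sdae_spec(config: SDAEConfig | None = None, grid: Sequence[int] | None = None) -> ModelSpec:
    base = config or SDAEConfig()

    def _fit(train: PatientCohort, depth: int | None, seed: int):
        cfg = SDAEConfig(**{**base.__dict__, "seed": seed})
        if depth is not None:
            cfg.n_coder_layers = depth
            widths = list(cfg.layer_widths) + [cfg.layer_widths[-1]] * depth
            cfg.layer_widths = widths[:depth]
        model = SDAEClassifier(train.m, cfg)
        return model.fit(train)

    def _score(model: SDAEClassifier, cohort: PatientCohort):
        pred = model.predict(cohort.X)
        return pred.probs, pred.labels

    return ModelSpec("SDAE", _fit, _score, grid)


def oracle_spec() -> ModelSpec:
    """A perfect oracle that returns the true labels — a harness sanity check."""

    def _fit(train: PatientCohort, depth: int | None, seed: int):
        return None

    def _score(model, cohort: PatientCohort):
        y = cohort.Y.astype(float)
        probs = np.clip(y, 0.01, 0.99)
        return probs, cohort.Y.copy()

    return ModelSpec("oracle", _fit, _score, None)


# ---------------------------------------------------------------------------
# protocol


def _cv_select_depth(
    spec: ModelSpec, train: PatientCohort, config: ProtocolConfig, seed: int
) -> int | None:
    """Pick the grid point with the best mean CV AUC (ties → shallower)."""
    if spec.grid is None:
        return None
    grid = list(spec.grid)
    if len(grid) == 1:
        return grid[0]
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(train.X, train.Y))
    best_depth, best_auc = grid[0], -np.inf
    for depth in grid:
        aucs = []
        for f, (tr, va) in enumerate(folds):
            fold_train = train.subset(tr)
            fold_val = train.subset(va)
            if len(np.unique(fold_val.Y)) < 2 or len(np.unique(fold_train.Y)) < 2:
                raise ValueError("a CV fold contains a single class; re-stratify")
            fitted = spec.fit(fold_train, depth, seed + 101 * f + depth)
            probs, _ = spec.score(fitted, fold_val)
            aucs.append(compute_auc(fold_val.Y, probs))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:
            best_auc = mean_auc
            best_depth = depth
    return best_depth


def run_protocol(
    cohort: PatientCohort,
    model_specs: Sequence[ModelSpec],
    config: ProtocolConfig | None = None,
) -> tuple[MetricsReport, list[TTestResult]]:
    """Repeated stratified-holdout evaluation with CV depth tuning.

    The 80/20 split is redrawn each repetition (seed = base_seed + r), so the
    mean ± std summaries reflect split-to-split variability. Test rows never
    influence training, standardization statistics or depth selection.
    """
    config = config or ProtocolConfig()
    config.validate()
    if not model_specs:
        raise ValueError("need at least one model spec")
    per_rep: dict[str, list[dict[str, float]]] = {s.name: [] for s in model_specs}
    depths: dict[str, list[int | None]] = {s.name: [] for s in model_specs}
    pooled_labels: dict[str, list[np.ndarray]] = {s.name: [] for s in model_specs}
    per_rep_labels: dict[str, list[np.ndarray]] = {s.name: [] for s in model_specs}

    for r in range(config.n_repeats):
        seed = config.base_seed + r
        train, test = split_holdout(cohort, config.train_fraction, seed=seed)
        if config.standardize:
            train, stats_used = standardize_features(train)
            test, _ = standardize_features(test, stats=stats_used)
        for spec in model_specs:
            depth = _cv_select_depth(spec, train, config, seed)
            fitted = spec.fit(train, depth, seed)
            probs, labels = spec.score(fitted, test)
            metrics = compute_metrics(test.Y, labels, probs)
            per_rep[spec.name].append(metrics)
            depths[spec.name].append(depth)
            pooled_labels[spec.name].append(np.asarray(labels))
            per_rep_labels[spec.name].append(np.asarray(labels))

    report = MetricsReport(per_rep, depths)
    ttests: list[TTestResult] = []
    names = [s.name for s in model_specs]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if config.ttest_mode == "pooled":
                va = np.concatenate(pooled_labels[a])
                vb = np.concatenate(pooled_labels[b])
                ttests.append(paired_t_test(va, vb, names=(a, b)))
            else:
                # one t-test per repetition; report the median-p repetition's result
                results = [
                    paired_t_test(la, lb, names=(a, b))
                    for la, lb in zip(per_rep_labels[a], per_rep_labels[b])
                ]
                ps = [res.p_value for res in results]
                ttests.append(results[int(np.argsort(ps)[len(ps) // 2])])
    return report, ttests


def ttest_matrix(results: Sequence[TTestResult], model_names: Sequence[str]) -> pd.DataFrame:
    """Upper-triangular p-value matrix across model pairs."""
    df = pd.DataFrame(index=list(model_names), columns=list(model_names), dtype=object)
    for res in results:
        a, b = res.model_pair
        df.loc[a, b] = res.p_value
    return df


def hidden_layer_sweep(
    cohort: PatientCohort,
    model_specs: Sequence[ModelSpec] | None = None,
    config: ProtocolConfig | None = None,
    model_config: ModelConfig | None = None,
    sdae_config: SDAEConfig | None = None,
    include_sdae: bool = False,
) -> pd.DataFrame:
    """Run the protocol at each fixed depth in the grid; tidy table per (model, depth).

    By default sweeps the attention model and the plain MLP over hidden-layer
    depths (and optionally SDAE over coder depths), emitting per-cell mean
    and std of every metric.
    """
    config = config or ProtocolConfig()
    config.validate()
    rows = []
    for depth in config.hidden_layer_grid:
        if model_specs is None:
            specs = [
                attention_spec(model_config, grid=[depth]),
                mlp_spec(model_config, grid=[depth]),
            ]
            if include_sdae:
                specs.append(sdae_spec(sdae_config, grid=[depth]))
        else:
            specs = [
                ModelSpec(s.name, s.fit, s.score, [depth] if s.grid is not None else None)
                for s in model_specs
            ]
        report, _ = run_protocol(cohort, specs, config)
        for name, metrics in report.summary().items():
            row: dict[str, object] = {"model": name, "depth": depth}
            for metric, (mean, std) in metrics.items():
                row[f"{metric}_mean"] = mean
                row[f"{metric}_std"] = std
            rows.append(row)
    return pd.DataFrame(rows)
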