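"""Synthetic patient cohorts with known informative features.

Emulates a numeric clinical feature table with a binary outcome: features are
(equicorrelated) standard Gaussians, the outcome follows a sparse logistic
model over a designated set of informative features, and missingness can be
injected completely at random. Because the informative set is known, both
prediction performance and attention faithfulness become testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data_io import PatientCohort, RawTable


@dataclass
class SyntheticSpec:
    """Parameters of the generative model.

    n, m
        patient and feature counts.
    informative_idx
        zero-based indices of the truly informative features.
    beta
        log-odds coefficient per informative feature.
    beta0
        intercept (log-odds); controls prevalence.
    feature_corr
        equicorrelation rho in [0, 1) among all features.
    missing_rate
        per-cell missingness probability in [0, 1).
    dichotomize_idx
        optional feature indices thresholded at 0 into {0,1} indicators,
        mimicking comorbidity flags.
    """

    n: int = 736
    m: int = 105
    informative_idx: Sequence[int] = ()
    beta: Sequence[float] = ()
    beta0: float = 0.0
    feature_corr: float = 0.0
    missing_rate: float = 0.0
    dichotomize_idx: Sequence[int] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 patients and m >= 1 features")
        idx = np.asarray(self.informative_idx, dtype=int)
        if len(idx) != len(self.beta):
            raise ValueError("beta must have one coefficient per informative feature")
        if idx.size and (idx.min() < 0 or idx.max() >= self.m):
            raise ValueError("informative_idx out of range")
        if len(set(idx.tolist())) != idx.size:
            raise ValueError("informative_idx contains duplicates")
        if not (0 <= self.feature_corr < 1):
            raise ValueError("feature_corr must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its generative ground truth."""

    cohort: PatientCohort
    raw: RawTable | None  # populated when missingness was injected
    truth_mask: np.ndarray
    true_probs: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)

    def save(self, directory: str | Path, label_name: str = "outcome") -> None:
        """Write the cohort CSV plus truth/spec JSON next to it."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(directory / "cohort.csv", label_name=label_name)
        truth = {
            "truth_mask": self.truth_mask.astype(bool).tolist(),
            "informative_features": [
                n for n, t in zip(self.cohort.feature_names, self.truth_mask) if t
            ],
            "spec": {
                "n": self.spec.n,
                "m": self.spec.m,
                "informative_idx": list(map(int, self.spec.informative_idx)),
                "beta": list(map(float, self.spec.beta)),
                "beta0": float(self.spec.beta0),
                "feature_corr": float(self.spec.feature_corr),
                "missing_rate": float(self.spec.missing_rate),
                "seed": int(self.spec.seed),
            },
        }
        (directory / "truth.json").write_text(json.dumps(truth, indent=2))


def _draw_features(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """Equicorrelated standard normals via the one-factor representation.

    X_j = sqrt(rho) * Z + sqrt(1-rho) * E_j gives corr(X_j, X_k) = rho for
    j != k with standard-normal margins.
    """
    eps = rng.standard_normal((n, m))
    if rho == 0:
        return eps
    z = rng.standard_normal((n, 1))
    return np.sqrt(rho) * z + np.sqrt(1 - rho) * eps


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a cohort from the logistic generative model, reproducibly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    X = _draw_features(rng, spec.n, spec.m, spec.feature_corr)
    for j in spec.dichotomize_idx:
        X[:, j] = (X[:, j] > 0).astype(float)
    eta = np.full(spec.n, spec.beta0, dtype=float)
    idx = np.asarray(spec.informative_idx, dtype=int)
    if idx.size:
        eta += X[:, idx] @ np.asarray(spec.beta, dtype=float)
    probs = expit(eta)
    Y = (rng.random(spec.n) < probs).astype(int)
    names = [f"f{j+1}" for j in range(spec.m)]
    mask = np.zeros(spec.m, dtype=bool)
    mask[idx] = True
    cohort = PatientCohort(X, names, Y)
    raw = None
    if spec.missing_rate > 0:
        raw = inject_missingness(cohort, spec.missing_rate, seed=spec.seed + 1)
    return SyntheticCohort(cohort, raw, mask, probs, spec)


def inject_missingness(
    cohort: PatientCohort, missing_rate: float, seed: int
) -> RawTable:
    """Mask feature cells completely at random; labels are never masked."""
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = cohort.X.copy()
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    return RawTable(values, list(cohort.feature_names), "outcome", cohort.Y.astype(float))


def solve_intercept(
    target_prevalence: float,
    informative_idx: Sequence[int],
    beta: Sequence[float],
    feature_corr: float = 0.0,
    tol: float = 1e-4,
    n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Find beta0 such that E[sigmoid(beta0 + beta'x)] matches a prevalence.

    Bisection on the Monte-Carlo expectation over the feature distribution;
    the expectation is monotone increasing in beta0, so bisection converges.
    """
    if not (0 < target_prevalence < 1):
        raise ValueError("target_prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    b = np.asarray(beta, dtype=float)
    k = len(b)
    if k:
        # only informative coordinates matter for the expectation
        Xi = _draw_features(rng, n_mc, k, feature_corr)
        lin = Xi @ b
    else:
        lin = np.zeros(n_mc)

    def prevalence(b0: float) -> float:
        return float(expit(b0 + lin).mean())

    lo, hi = -20.0, 20.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if prevalence(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def study_shaped_spec(
    seed: int = 0,
    n: int = 736,
    m: int = 105,
    n_informative: int = 10,
    beta_scale: float = 0.8,
    target_prevalence: float = 461 / 736,
    feature_corr: float = 0.0,
    missing_rate: float = 0.0,
) -> SyntheticSpec:
    """A cohort shaped like a small heart-failure readmission study:
    736 patients, 105 features, ~0.63 event prevalence, a handful of truly
    predictive features with alternating-sign effects.
    """
    informative_idx = list(range(n_informative))
    beta = [beta_scale * (1 if j % 2 == 0 else -1) for j in range(n_informative)]
    beta0 = solve_intercept(target_prevalence, informative_idx, beta, feature_corr)
    return SyntheticSpec(
        n=n,
        m=m,
        informative_idx=informative_idx,
        beta=beta,
        beta0=beta0,
        feature_corr=feature_corr,
        missing_rate=missing_rate,
        seed=seed,
    )
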