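"""Tabular patient data: parsing, missingness filtering, imputation, scaling, splitting.

The preprocessing pipeline mirrors common clinical-table practice: features
with more than a given fraction of missing values are dropped outright, the
remainder are filled with the per-feature median, and features are z-scored
with training-split statistics before model fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

DEFAULT_MISSING_MARKERS = frozenset({"", "NA", "NaN"})


class DataError(ValueError):
    """Raised for malformed tables or contract violations in preprocessing."""


@dataclass
class RawTable:
    """A parsed feature table that may still contain missing cells.

    ``values`` is an n x m float array where missing cells are ``np.nan``.
    ``labels`` is a length-n float array, ``np.nan`` marking a missing label.
    """

    values: np.ndarray
    feature_names: list[str]
    label_name: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D grid")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise DataError("table must have at least one row and one column")
        if len(self.feature_names) != m:
            raise DataError("feature_names length does not match column count")
        if len(set(self.feature_names)) != m:
            dupes = {f for f in self.feature_names if self.feature_names.count(f) > 1}
            raise DataError(f"duplicated feature names: {sorted(dupes)}")
        if self.labels.shape != (n,):
            raise DataError("labels length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def missing_fractions(self) -> np.ndarray:
        """Per-feature fraction of missing cells."""
        return np.isnan(self.values).mean(axis=0)


@dataclass
class PatientCohort:
    """A complete numeric cohort: feature matrix X with binary labels Y.

    Labels use the convention 1 = event (e.g. readmitted), 0 = no event.
    """

    X: np.ndarray
    feature_names: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y)
        if self.X.ndim != 2:
            raise DataError("X must be 2-D")
        if np.isnan(self.X).any():
            raise DataError("PatientCohort must not contain missing values")
        if len(self.feature_names) != self.X.shape[1]:
            raise DataError("feature_names length does not match X")
        if self.Y.shape != (self.X.shape[0],):
            raise DataError("Y length does not match X")
        if not np.isin(self.Y, (0, 1)).all():
            raise DataError("labels must be strictly binary (0/1)")
        self.Y = self.Y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "PatientCohort":
        return PatientCohort(self.X[idx], list(self.feature_names), self.Y[idx])

    def to_frame(self, label_name: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_name] = self.Y
        return df

    def to_csv(self, path: str | Path, label_name: str = "outcome") -> None:
        self.to_frame(label_name).to_csv(path, index=False)


@dataclass
class PreprocessReport:
    """Record of what the missingness filter and imputation did."""

    dropped_features: list[tuple[str, float]] = field(default_factory=list)
    imputation_medians: dict[str, float] = field(default_factory=dict)
    n_rows: int = 0
    n_cols_before: int = 0
    n_cols_after: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dropped_features": [
                {"name": n, "missing_fraction": f} for n, f in self.dropped_features
            ],
            "imputation_medians": self.imputation_medians,
            "n_rows": self.n_rows,
            "n_cols_before": self.n_cols_before,
            "n_cols_after": self.n_cols_after,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_feature_table(
    path: str | Path,
    label_name: str,
    missing_markers: Iterable[str] = DEFAULT_MISSING_MARKERS,
    delimiter: str | None = None,
) -> RawTable:
    """Read a delimited text table with a header row into a :class:`RawTable`.

    Cells whose stripped text matches one of ``missing_markers`` (the empty
    cell included by default) are recorded as missing. The label column is
    separated from the features. Non-numeric cells that are not missing
    markers raise :class:`DataError` naming the offending column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    markers = {str(s) for s in missing_markers}
    sep = delimiter if delimiter is not None else ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise DataError(f"duplicated header names: {dupes}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if label_name not in cols:
        raise DataError(f"label column {label_name!r} not found in header {cols}")

    def parse_column(col: pd.Series, name: str) -> np.ndarray:
        raw = col.str.strip()
        is_missing = raw.isin(markers)
        out = np.full(len(raw), np.nan)
        numeric = pd.to_numeric(raw[~is_missing], errors="coerce")
        if numeric.isna().any():
            bad_row = int(numeric.index[numeric.isna()][0])
            raise DataError(
                f"non-numeric cell {raw.iloc[bad_row]!r} in column {name!r} at row {bad_row}"
            )
        out[~is_missing.to_numpy()] = numeric.to_numpy()
        return out

    feature_names = [c for c in cols if c != label_name]
    if not feature_names:
        raise DataError("table has no feature columns")
    values = np.column_stack([parse_column(df[c], c) for c in feature_names])
    labels = parse_column(df[label_name], label_name)
    return RawTable(values, feature_names, label_name, labels)


def filter_missing_features(
    raw: RawTable, max_missing_fraction: float = 0.30
) -> tuple[RawTable, PreprocessReport]:
    """Drop features whose missing fraction is strictly greater than the threshold.

    The boundary is deliberate: a feature missing exactly at the threshold is
    retained (the rule is "more than"). Retained-feature order is preserved.
    """
    if not (0 <= max_missing_fraction < 1):
        raise DataError("max_missing_fraction must be in [0, 1)")
    fracs = raw.missing_fractions()
    keep = fracs <= max_missing_fraction
    if not keep.any():
        raise DataError("all features exceed the missingness threshold; nothing remains")
    report = PreprocessReport(
        dropped_features=[
            (name, float(f))
            for name, f, k in zip(raw.feature_names, fracs, keep)
            if not k
        ],
        n_rows=raw.n,
        n_cols_before=raw.m,
        n_cols_after=int(keep.sum()),
    )
    filtered = RawTable(
        raw.values[:, keep],
        [n for n, k in zip(raw.feature_names, keep) if k],
        raw.label_name,
        raw.labels,
    )
    return filtered, report


def impute_median(
    raw: RawTable, report: PreprocessReport | None = None
) -> PatientCohort:
    """Replace each missing cell with the median of its feature's observed values.

    Medians are computed over all rows of ``raw`` (dataset-level imputation).
    For a leakage-free protocol compute medians on a training split and apply
    them to held-out data via the ``medians`` returned in the report.
    """
    if np.isnan(raw.labels).any():
        bad = int(np.flatnonzero(np.isnan(raw.labels))[0])
        raise DataError(f"missing label at row {bad}")
    values = raw.values.copy()
    medians: dict[str, float] = {}
    for j, name in enumerate(raw.feature_names):
        col = values[:, j]
        mask = np.isnan(col)
        if mask.all():
            raise DataError(
                f"feature {name!r} is fully missing; it should have been filtered"
            )
        if mask.any():
            med = float(np.median(col[~mask]))
            col[mask] = med
            medians[name] = med
    if report is not None:
        report.imputation_medians = medians
    return PatientCohort(values, list(raw.feature_names), raw.labels)


def preprocess(
    raw: RawTable, max_missing_fraction: float = 0.30
) -> tuple[PatientCohort, PreprocessReport]:
    """Convenience composition: missingness filter followed by median imputation."""
    filtered, report = filter_missing_features(raw, max_missing_fraction)
    cohort = impute_median(filtered, report)
    return cohort, report


def standardize_features(
    cohort: PatientCohort,
    stats: Sequence[tuple[float, float]] | None = None,
) -> tuple[PatientCohort, list[tuple[float, float]]]:
    """z-score each feature, returning the (mean, sd) pairs used.

    When ``stats`` is supplied (e.g. training-split statistics applied to a
    test split) it is used verbatim; otherwise statistics are computed from
    the input with the sample-sd (ddof=1) convention. A zero-sd feature is
    centered but left unscaled.
    """
    if stats is None:
        means = cohort.X.mean(axis=0)
        sds = cohort.X.std(axis=0, ddof=1) if cohort.n > 1 else np.zeros(cohort.m)
        used = list(zip(means.tolist(), sds.tolist()))
    else:
        if len(stats) != cohort.m:
            raise DataError(
                f"stats has {len(stats)} entries but cohort has {cohort.m} features"
            )
        used = [(float(mu), float(sd)) for mu, sd in stats]
        means = np.array([mu for mu, _ in used])
        sds = np.array([sd for _, sd in used])
    denom = np.where(sds == 0, 1.0, sds)
    X = (cohort.X - means) / denom
    return PatientCohort(X, list(cohort.feature_names), cohort.Y), used


def split_holdout(
    cohort: PatientCohort, train_fraction: float = 0.8, seed: int = 0
) -> tuple[PatientCohort, PatientCohort]:
    """Stratified train/test split, deterministic given ``seed``."""
    if not (0 < train_fraction < 1):
        raise DataError("train_fraction must be in (0, 1)")
    classes = np.unique(cohort.Y)
    if len(classes) < 2:
        raise DataError("both outcome classes must be present to split")
    idx = np.arange(cohort.n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=cohort.Y,
        random_state=seed,
    )
    return cohort.subset(np.sort(train_idx)), cohort.subset(np.sort(test_idx))


def cohort_from_frame(
    df: pd.DataFrame, label_name: str = "outcome"
) -> PatientCohort:
    """Build a cohort from an in-memory DataFrame with a binary label column."""
    if label_name not in df.columns:
        raise DataError(f"label column {label_name!r} not found")
    feats = [c for c in df.columns if c != label_name]
    return PatientCohort(
        df[feats].to_numpy(dtype=float), feats, df[label_name].to_numpy()
    )
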