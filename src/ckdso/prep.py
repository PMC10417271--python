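"""Leakage-safe preparation pipeline for clinical tables.

Every statistic (imputation values, encoder level maps, standardisation
moments, the outlier model) is fitted on the training partition only and
frozen into :class:`PrepState`; the test partition is transformed with that
state and is never filtered, deduplicated or resampled.

Stage order: impute -> LOF outlier removal (train only) -> deduplicate
(train only) -> one-hot encode -> SMOTE balancing (train only) ->
z-score standardisation.  Typo correction, numeric coercion and the
stratified split happen upstream (see :mod:`ckdso.dataio` and
:func:`split_train_test`); splitting before any fitting is what makes the
no-leakage contract satisfiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import train_test_split

from .dataio import DataMatrix

__all__ = [
    "PrepConfig",
    "PrepState",
    "PrepReport",
    "split_train_test",
    "fit_imputer",
    "apply_imputer",
    "lof_scores",
    "remove_outliers",
    "drop_duplicates",
    "smote_balance",
    "fit_encoder",
    "onehot_encode",
    "fit_scaler",
    "zscore",
    "fit_pipeline",
    "apply_pipeline",
]

# Matches the density regulariser used throughout the LOF literature's
# reference implementations; keeps lrd finite on duplicate-heavy data.
_LRD_EPS = 1e-10


@dataclass
class PrepConfig:
    impute_numeric: str = "mean"
    impute_categorical: str = "backfill"
    lof_neighbors: int = 20
    lof_columns: tuple[str, ...] = ("age", "hemo", "pcv", "rc", "sg")
    lof_contamination: float = 0.065  # ~26 flagged of 400
    dedupe: bool = True
    balance: str = "smote"
    smote_neighbors: int = 5
    encode: str = "onehot"
    standardize: bool = True
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0 <= self.lof_contamination < 0.5:
            raise ValueError("lof_contamination must be in [0, 0.5)")
        if self.impute_numeric != "mean":
            raise ValueError("only mean numeric imputation is supported")
        if self.impute_categorical != "backfill":
            raise ValueError("only backfill categorical imputation is supported")
        if self.balance not in ("smote", "none"):
            raise ValueError("balance must be 'smote' or 'none'")
        if self.lof_neighbors < 1 or self.smote_neighbors < 1:
            raise ValueError("neighbor counts must be positive")


@dataclass
class PrepState:
    """Statistics frozen from the training partition."""

    numeric_means: dict[str, float] = field(default_factory=dict)
    categorical_fill: dict[str, list[float]] = field(default_factory=dict)
    categorical_mode: dict[str, float] = field(default_factory=dict)
    encoder_levels: dict[str, list[str]] = field(default_factory=dict)
    positive_level_code: dict[str, float] = field(default_factory=dict)
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    scaled_names: list[str] = field(default_factory=list)
    lof_summary: dict = field(default_factory=dict)
    fitted_rows: int = 0
    config: PrepConfig | None = None


@dataclass
class PrepReport:
    imputed_cells: dict[str, int] = field(default_factory=dict)
    lof_flagged: list[int] = field(default_factory=list)
    duplicates_removed: int = 0
    class_counts_before: tuple[int, int] = (0, 0)
    class_counts_after: tuple[int, int] = (0, 0)
    synthetic_rows_added: int = 0
    unseen_levels: list[tuple[int, str, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "imputed_cells": dict(self.imputed_cells),
            "imputed_total": int(sum(self.imputed_cells.values())),
            "lof_flagged_rows": list(map(int, self.lof_flagged)),
            "lof_flagged_count": len(self.lof_flagged),
            "duplicates_removed": self.duplicates_removed,
            "class_counts_before": list(self.class_counts_before),
            "class_counts_after": list(self.class_counts_after),
            "synthetic_rows_added": self.synthetic_rows_added,
        }


def split_train_test(
    data: DataMatrix, fraction: float = 0.8, seed: int = 0
) -> tuple[DataMatrix, DataMatrix]:
    """Stratified shuffled partition into train/test by ``fraction``."""
    if data.n_samples == 0:
        raise ValueError("cannot split an empty matrix")
    neg, pos = data.class_counts()
    if min(neg, pos) < 2:
        raise ValueError("each class needs at least 2 members to stratify")
    idx = np.arange(data.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=fraction,
        random_state=seed,
        shuffle=True,
        stratify=data.y,
    )
    return data.take(np.sort(train_idx)), data.take(np.sort(test_idx))


# ---------------------------------------------------------------- imputation

def fit_imputer(train: DataMatrix, config: PrepConfig) -> PrepState:
    """Store per-column imputation values from the training partition.

    Numeric columns keep their arithmetic mean over observed cells.
    Categorical/boolean columns keep the observed code sequence (enabling
    the backward fill used on the training partition itself) and its modal
    code (used for any other partition, so only training statistics are
    consulted at apply time).
    """
    state = PrepState(config=config, fitted_rows=train.n_samples)
    for j, name in enumerate(train.feature_names):
        col = train.X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"column {name!r} is entirely missing in training data")
        if train.column_kinds[j] == "numeric":
            state.numeric_means[name] = float(obs.mean())
        else:
            state.categorical_fill[name] = [float(v) for v in obs]
            codes, counts = np.unique(obs, return_counts=True)
            state.categorical_mode[name] = float(codes[np.argmax(counts)])
    return state


def _backfill(col: np.ndarray) -> np.ndarray:
    """Missing cell takes the next observed value; trailing take the previous."""
    out = col.copy()
    nxt = np.nan
    for i in range(len(out) - 1, -1, -1):
        if np.isnan(out[i]):
            out[i] = nxt
        else:
            nxt = out[i]
    prev = np.nan
    for i in range(len(out)):
        if np.isnan(out[i]):
            out[i] = prev
        else:
            prev = out[i]
    return out


def apply_imputer(
    data: DataMatrix,
    state: PrepState,
    is_train: bool,
    report: PrepReport | None = None,
) -> DataMatrix:
    X = data.X.copy()
    for j, name in enumerate(data.feature_names):
        miss = np.isnan(X[:, j])
        if report is not None and miss.any():
            report.imputed_cells[name] = (
                report.imputed_cells.get(name, 0) + int(miss.sum())
            )
        if not miss.any():
            continue
        if data.column_kinds[j] == "numeric":
            X[miss, j] = state.numeric_means[name]
        elif is_train:
            X[:, j] = _backfill(X[:, j])
        else:
            X[miss, j] = state.categorical_mode[name]
    return DataMatrix(
        list(data.feature_names), X, data.y.copy(), list(data.column_kinds),
        {k: list(v) for k, v in data.level_maps.items()},
    )


# --------------------------------------------------------------------- LOF

def lof_scores(X: np.ndarray, k: int) -> np.ndarray:
    """Local outlier factor with Euclidean metric.

    For each point: the k-distance neighbourhood (all points within the
    k-th nearest distance, so ties enlarge it), reachability distances,
    local reachability density lrd = 1 / (mean reach-dist + eps), and the
    score = mean(lrd of neighbours) / lrd(self).  Inliers score ~1,
    outliers well above 1.  O(n^2) distances; fine for cohort-sized n.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rows, got {n}")
    if np.isnan(X).any():
        raise ValueError("lof_scores requires imputed (complete) data")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    kdist = D[np.arange(n), order[:, k - 1]]

    neighborhoods = [np.flatnonzero(D[i] <= kdist[i]) for i in range(n)]
    lrd = np.empty(n)
    for i, nb in enumerate(neighborhoods):
        reach = np.maximum(kdist[nb], D[i, nb])
        lrd[i] = 1.0 / (reach.mean() + _LRD_EPS)
    scores = np.empty(n)
    for i, nb in enumerate(neighborhoods):
        scores[i] = (lrd[nb] / lrd[i]).mean()
    return scores


def remove_outliers(
    train: DataMatrix, config: PrepConfig
) -> tuple[DataMatrix, list[int]]:
    """Drop the top ceil(contamination * n) LOF-ranked training rows.

    Scored on the configured LOF columns only (falling back to all numeric
    columns when none of the configured names are present, as for synthetic
    cohorts with generated feature names).
    """
    if config.lof_contamination == 0:
        return train, []
    cols = [c for c in config.lof_columns if c in train.feature_names]
    if not cols:
        cols = [
            n for n, k in zip(train.feature_names, train.column_kinds)
            if k == "numeric"
        ]
    idx = [train.feature_names.index(c) for c in cols]
    sub = train.X[:, idx]
    # scale columns so the Euclidean metric is not dominated by units
    sd = sub.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scores = lof_scores((sub - sub.mean(axis=0)) / sd, config.lof_neighbors)
    n = train.n_samples
    n_flag = int(np.ceil(config.lof_contamination * n))
    flagged = np.argsort(-scores, kind="stable")[:n_flag]
    keep = np.setdiff1d(np.arange(n), flagged)
    kept = train.take(keep)
    neg, pos = kept.class_counts()
    if neg == 0 or pos == 0:
        raise ValueError("lof_contamination removed an entire class")
    return kept, sorted(int(i) for i in flagged)


def drop_duplicates(train: DataMatrix) -> tuple[DataMatrix, int]:
    """Remove exact duplicate feature+label rows, keeping first occurrences."""
    rows = np.column_stack([train.X, train.y])
    seen: set[bytes] = set()
    keep = []
    for i in range(rows.shape[0]):
        key = rows[i].tobytes()
        if key not in seen:
            seen.add(key)
            keep.append(i)
    removed = rows.shape[0] - len(keep)
    return train.take(np.array(keep, dtype=int)), removed


# ------------------------------------------------------------------- SMOTE

def smote_balance(train: DataMatrix, k: int = 5, seed: int = 0) -> DataMatrix:
    """Synthetic minority oversampling until classes are exactly equal.

    Each synthetic sample interpolates a random minority row x toward one
    of its k nearest minority neighbours x' (Euclidean): x + u (x' - x),
    u ~ Uniform(0, 1).  Applied to the training partition only.
    """
    neg, pos = train.class_counts()
    if neg == pos:
        return train
    minority = 1 if pos < neg else 0
    need = abs(neg - pos)
    m_idx = np.flatnonzero(train.y == minority)
    if len(m_idx) < k + 1:
        raise ValueError(
            f"minority class has {len(m_idx)} members; needs >= k+1={k + 1} "
            "(use a smaller smote_neighbors)"
        )
    rng = np.random.default_rng(seed)
    M = train.X[m_idx]
    D = cdist(M, M)
    np.fill_diagonal(D, np.inf)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    base = rng.integers(0, len(m_idx), size=need)
    pick = rng.integers(0, k, size=need)
    u = rng.uniform(0.0, 1.0, size=need)
    Xnew = M[base] + u[:, None] * (M[nn[base, pick]] - M[base])
    X = np.vstack([train.X, Xnew])
    y = np.concatenate([train.y, np.full(need, minority, dtype=int)])
    return DataMatrix(
        list(train.feature_names), X, y, list(train.column_kinds),
        {k_: list(v) for k_, v in train.level_maps.items()},
    )


# ---------------------------------------------------------------- encoding

_POSITIVE_TOKENS = {"yes", "present", "good", "true", "1", "abnormal"}


def fit_encoder(train: DataMatrix, state: PrepState) -> PrepState:
    """Record the one-hot layout from training-partition levels.

    Binary categoricals map to a single 0/1 column (the 'yes'-type level is
    1); wider categoricals get one indicator column per observed level.
    """
    for j, name in enumerate(train.feature_names):
        if train.column_kinds[j] == "numeric":
            continue
        lvls = train.level_maps.get(name)
        codes = sorted(float(v) for v in np.unique(train.X[:, j]) if not np.isnan(v))
        if lvls is None:
            lvls = [str(int(c)) for c in codes]
        observed = [lvls[int(c)] if int(c) < len(lvls) else str(c) for c in codes]
        state.encoder_levels[name] = observed
        if len(observed) == 2:
            pos = [lv for lv in observed if lv.lower() in _POSITIVE_TOKENS]
            pos_level = pos[0] if pos else observed[1]
            state.positive_level_code[name] = float(codes[observed.index(pos_level)])
    return state


def onehot_encode(
    data: DataMatrix, state: PrepState, report: PrepReport | None = None
) -> DataMatrix:
    """Apply the fitted 0/1 encoding; unseen levels give all-zero indicators."""
    names, kinds, cols = [], [], []
    for j, name in enumerate(data.feature_names):
        col = data.X[:, j]
        if data.column_kinds[j] == "numeric":
            names.append(name)
            kinds.append("numeric")
            cols.append(col)
            continue
        lvls = data.level_maps.get(name, [])
        observed = state.encoder_levels.get(name, [])
        code_of = {lv: float(i) for i, lv in enumerate(lvls)}
        train_codes = [code_of.get(lv, np.nan) for lv in observed]
        unseen_rows = [
            i for i, c in enumerate(col)
            if not np.isnan(c) and c not in train_codes
        ]
        if report is not None:
            for i in unseen_rows:
                report.unseen_levels.append((i, name, float(col[i])))
        if name in state.positive_level_code:
            names.append(name)
            kinds.append("numeric")
            cols.append((col == state.positive_level_code[name]).astype(float))
        else:
            for lv, code in zip(observed, train_codes):
                names.append(f"{name}={lv}")
                kinds.append("numeric")
                cols.append((col == code).astype(float))
    X = np.column_stack(cols) if cols else np.empty((data.n_samples, 0))
    return DataMatrix(names, X, data.y.copy(), kinds, {})


# ----------------------------------------------------------- standardise

def fit_scaler(train: DataMatrix, state: PrepState) -> PrepState:
    """Freeze per-column mean and population SD (ddof=0) from training data."""
    state.mu = train.X.mean(axis=0)
    state.sigma = train.X.std(axis=0, ddof=0)
    state.scaled_names = list(train.feature_names)
    return state


def zscore(data: DataMatrix, state: PrepState) -> DataMatrix:
    """z = (x - mu) / sigma with the frozen training moments.

    Constant training columns (sigma = 0) map to 0 with a warning.
    """
    if state.mu is None or state.sigma is None:
        raise ValueError("scaler not fitted")
    if list(data.feature_names) != state.scaled_names:
        raise ValueError("column layout differs from the fitted scaler")
    sigma = state.sigma.copy()
    zero = sigma == 0
    if zero.any():
        warnings.warn(
            "constant training column(s) mapped to 0: "
            + ", ".join(np.array(data.feature_names)[zero]),
            stacklevel=2,
        )
        sigma[zero] = 1.0
    Z = (data.X - state.mu) / sigma
    Z[:, zero] = 0.0
    return DataMatrix(
        list(data.feature_names), Z, data.y.copy(), list(data.column_kinds), {}
    )


# ----------------------------------------------------------------- pipeline

def fit_pipeline(
    train: DataMatrix, config: PrepConfig
) -> tuple[PrepState, DataMatrix, PrepReport]:
    """Fit all stages on the training partition and return its transform."""
    report = PrepReport()
    state = fit_imputer(train, config)
    cur = apply_imputer(train, state, is_train=True, report=report)
    if config.lof_contamination > 0:
        cur, flagged = remove_outliers(cur, config)
        report.lof_flagged = flagged
        state.lof_summary = {
            "neighbors": config.lof_neighbors,
            "contamination": config.lof_contamination,
            "flagged": len(flagged),
        }
    if config.dedupe:
        cur, removed = drop_duplicates(cur)
        report.duplicates_removed = removed
    state = fit_encoder(cur, state)
    cur = onehot_encode(cur, state, report)
    report.class_counts_before = cur.class_counts()
    if config.balance == "smote":
        before = cur.n_samples
        cur = smote_balance(cur, k=config.smote_neighbors, seed=config.seed)
        report.synthetic_rows_added = cur.n_samples - before
    report.class_counts_after = cur.class_counts()
    if config.standardize:
        state = fit_scaler(cur, state)
        cur = zscore(cur, state)
    return state, cur, report


def apply_pipeline(
    test: DataMatrix, state: PrepState, report: PrepReport | None = None
) -> DataMatrix:
    """Transform a held-out partition with frozen training statistics.

    No fitting, no outlier removal, no deduplication, no balancing.
    """
    if state.config is None:
        raise ValueError("PrepState carries no config; fit_pipeline it first")
    cur = apply_imputer(test, state, is_train=False, report=report)
    cur = onehot_encode(cur, state, report)
    if state.config.standardize:
        cur = zscore(cur, state)
    return cur
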