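"""Subject-level discrimination by repeated cross-validated gradient boosting.

Each binary contrast (e.g. PD vs HC) is evaluated with stratified
5-fold cross-validation repeated over many random partitions.  Within
every training split: feature-wise min-max normalization is fitted,
missing cells are imputed with the training median, and a gradient
boosted tree classifier is fitted (optionally after a small inner
grid search).  Test-fold probability scores are pooled per iteration
into one AUC; the report carries the full AUC list so the mean +- SD is
recomputable.

Normalization, imputation and tuning see training folds only; a
``paper_mode`` switch instead fits the normalizer on the full sample,
mirroring analyses that normalize before partitioning, for faithfulness
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

DEFAULT_GRID = {
    "max_depth": [2, 3],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50],
}


@dataclass
class MinMaxNormalizer:
    """Affine rescaling to [0, 1] by training-set extrema, per feature.

    A constant training feature maps everything to 0; out-of-range
    values are not clipped.
    """

    mins: np.ndarray = field(default_factory=lambda: np.array([]))
    ranges: np.ndarray = field(default_factory=lambda: np.array([]))

    def fit(self, train: np.ndarray) -> "MinMaxNormalizer":
        train = np.asarray(train, dtype=float)
        if train.size == 0 or train.shape[0] < 1:
            raise ValueError("cannot fit normalizer on empty training data")
        self.mins = np.nanmin(train, axis=0)
        self.ranges = np.nanmax(train, axis=0) - self.mins
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        safe = np.where(self.ranges == 0, 1.0, self.ranges)
        out = (values - self.mins) / safe
        if out.ndim == 1:
            out = np.where(self.ranges == 0, 0.0, out)
        else:
            out[:, self.ranges == 0] = 0.0
        return out


def minmax_normalize(train: Sequence[float], apply_to: Sequence[float]) -> np.ndarray:
    """(x - min_train) / (max_train - min_train); constant train maps to 0."""
    train = np.asarray(train, dtype=float)
    if train.size < 2:
        raise ValueError("min-max normalization needs >=2 training values")
    return MinMaxNormalizer().fit(train.reshape(-1, 1)).transform(
        np.asarray(apply_to, dtype=float).reshape(-1, 1)
    ).ravel()


@dataclass
class ClassifierReport:
    """Per-iteration AUCs and pooled decision scores for one group pair."""

    pair: str
    aucs: list[float]
    mean_auc: float
    sd_auc: float
    decision_scores: pd.DataFrame  # participant_id, label, mean_score
    hyperparameters: list[dict]
    seed: int
    n_folds: int
    n_iterations: int


def _grid_candidates(grid: dict) -> list[dict]:
    keys = sorted(grid)
    combos = [{}]
    for k in keys:
        combos = [dict(c, **{k: v}) for c in combos for v in grid[k]]
    return combos


def _tune(x: np.ndarray, y: np.ndarray, grid: Optional[dict], rng_seed: int) -> dict:
    """Inner 3-fold grid search on training data; {} = library defaults."""
    if not grid:
        return {}
    candidates = _grid_candidates(grid)
    if len(candidates) == 1:
        return candidates[0]
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=rng_seed)
    best, best_auc = candidates[0], -np.inf
    for cand in candidates:
        scores = []
        for tr, te in inner.split(x, y):
            if len(np.unique(y[te])) < 2:
                continue
            model = GradientBoostingClassifier(random_state=rng_seed, **cand)
            model.fit(x[tr], y[tr])
            scores.append(roc_auc_score(y[te], model.predict_proba(x[te])[:, 1]))
        mean = np.mean(scores) if scores else -np.inf
        if mean > best_auc:
            best, best_auc = cand, mean
    return best


def crossval_classify(
    features: pd.DataFrame,
    pair: tuple[str, str],
    feature_columns: Sequence[str],
    group_col: str = "group",
    id_col: str = "participant_id",
    n_folds: int = 5,
    n_iterations: int = 1000,
    tuning_grid: Optional[dict] = None,
    seed: int = 0,
    paper_mode: bool = False,
) -> ClassifierReport:
    """Repeated stratified k-fold gradient-boosting classification.

    Parameters
    ----------
    features
        FeatureMatrix rows; only the two groups in ``pair`` are used.
    tuning_grid
        Hyperparameter grid for the inner 3-fold search on training
        folds; None fits library defaults (no search).
    paper_mode
        Fit the min-max normalizer on the full sample instead of the
        training folds.

    Returns a ClassifierReport with one AUC per iteration (pooled
    out-of-fold scores) and per-subject mean decision scores.
    """
    sub = features[features[group_col].isin(pair)].reset_index(drop=True)
    y = (sub[group_col] == pair[0]).to_numpy(dtype=int)
    x_raw = sub[list(feature_columns)].to_numpy(dtype=float)
    ids = sub[id_col].to_numpy()
    for lab, n in zip(pair, [int(y.sum()), int((1 - y).sum())]):
        if n < n_folds:
            raise ValueError(f"group {lab} has {n} members; needs >= n_folds={n_folds}")
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    chosen: list[dict] = []
    score_sum = np.zeros(len(y))
    score_n = np.zeros(len(y))
    full_normalizer = MinMaxNormalizer().fit(x_raw) if paper_mode else None
    for _ in range(n_iterations):
        it_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=it_seed)
        pooled_scores = np.empty(len(y))
        for tr, te in skf.split(x_raw, y):
            x_tr = x_raw[tr].copy()
            x_te = x_raw[te].copy()
            med = np.nanmedian(x_tr, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            for arr in (x_tr, x_te):
                nan_r, nan_c = np.nonzero(np.isnan(arr))
                arr[nan_r, nan_c] = med[nan_c]
            norm = full_normalizer if paper_mode else MinMaxNormalizer().fit(x_tr)
            x_tr = norm.transform(x_tr)
            x_te = norm.transform(x_te)
            params = _tune(x_tr, y[tr], tuning_grid, it_seed)
            model = GradientBoostingClassifier(random_state=it_seed, **params)
            model.fit(x_tr, y[tr])
            pooled_scores[te] = model.predict_proba(x_te)[:, 1]
            chosen.append(params)
        aucs.append(float(roc_auc_score(y, pooled_scores)))
        score_sum += pooled_scores
        score_n += 1
    decision = pd.DataFrame(
        {
            "participant_id": ids,
            "label": np.where(y == 1, pair[0], pair[1]),
            "mean_score": score_sum / score_n,
        }
    )
    return ClassifierReport(
        pair=f"{pair[0]}-vs-{pair[1]}",
        aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        decision_scores=decision,
        hyperparameters=chosen,
        seed=seed,
        n_folds=n_folds,
        n_iterations=n_iterations,
    )
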