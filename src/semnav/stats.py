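"""Group-level inference: outlier fencing, ANCOVA, Tukey HSD, correlations.

The inferential stage compares each feature between groups with a
one-way ANCOVA (group factor + years-of-education covariate), after
removing points outside a 3 x IQR fence, and follows significant
omnibus effects with Tukey-Kramer post hocs and Cohen's d.  Clinical
correlations pool each patient group with controls ("tandems") and use
Pearson or Spearman depending on Shapiro-Wilk normality of both
variables; an optional covariate is partialled out by residualization.

The ANCOVA is computed directly from two least-squares fits (covariate
only vs covariate + group dummies); the group F test is therefore the
Type-II sum-of-squares test, and partial eta squared is
SS_group / (SS_group + SS_error).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class PostHoc:
    pair: tuple[str, str]
    p_value: float
    cohens_d: float
    mean_diff: float


@dataclass
class GroupComparison:
    """Omnibus ANCOVA result for one feature, with post hocs."""

    feature: str
    f_statistic: float
    p_value: float
    partial_eta_squared: float
    posthoc: list[PostHoc] = field(default_factory=list)
    n_outliers_removed: int = 0
    n_used: int = 0


@dataclass
class CorrelationResult:
    feature: str
    clinical_score: str
    tandem: str
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int
    covariate: Optional[str] = None


def remove_outliers(values: Sequence[float], k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass interquartile fencing.

    Retains x with Q1 - k*IQR <= x <= Q3 + k*IQR, quartiles by linear
    interpolation on the full input (no iteration).  Returns
    ``(retained_values, removed_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 4:
        raise ValueError("remove_outliers needs at least 4 finite values")
    q1, q3 = np.percentile(x[np.isfinite(x)], [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (x >= lo) & (x <= hi)
    removed = np.flatnonzero(~keep & np.isfinite(x))
    return x[keep], removed


def _ancova_fit(y: np.ndarray, groups: np.ndarray, cov: Optional[np.ndarray]):
    """Residual sums of squares of the reduced (no group) and full models."""
    n = len(y)
    intercept = np.ones((n, 1))
    parts_reduced = [intercept]
    if cov is not None:
        parts_reduced.append(cov.reshape(-1, 1))
    labels = pd.unique(groups)
    dummies = np.column_stack([(groups == g).astype(float) for g in labels[1:]])
    x_reduced = np.hstack(parts_reduced)
    x_full = np.hstack([x_reduced, dummies])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("design matrix is rank-deficient (covariate collinear with group?)")
    for x in (x_reduced, x_full):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        yield float(resid @ resid), x.shape[1]


def ancova_oneway(
    values: Sequence[float],
    groups: Sequence[str],
    covariate: Optional[Sequence[float]] = None,
    feature: str = "",
) -> GroupComparison:
    """One-way ANCOVA F test for the group factor, adjusting for a covariate.

    With no covariate this reduces to the one-way ANOVA.  Partial eta
    squared is SS_group / (SS_group + SS_error).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    cov = None if covariate is None else np.asarray(covariate, dtype=float)
    mask = np.isfinite(y)
    if cov is not None:
        if not np.all(np.isfinite(cov[mask])):
            raise ValueError("covariate contains non-finite values")
        mask &= np.isfinite(cov)
    y, g = y[mask], g[mask]
    cov = None if cov is None else cov[mask]
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("need >=2 groups with >=2 observations each")
    (rss_reduced, _), (rss_full, p_full) = _ancova_fit(y, g, cov)
    df_group = len(labels) - 1
    df_error = len(y) - p_full
    ss_group = rss_reduced - rss_full
    ms_group = ss_group / df_group
    ms_error = rss_full / df_error
    if ms_error == 0:
        f_stat = math.inf if ms_group > 0 else 0.0
        p = 0.0 if ms_group > 0 else 1.0
    else:
        f_stat = ms_group / ms_error
        p = float(sps.f.sf(f_stat, df_group, df_error))
    eta = ss_group / (ss_group + rss_full) if (ss_group + rss_full) > 0 else 0.0
    return GroupComparison(
        feature=feature,
        f_statistic=float(f_stat),
        p_value=p,
        partial_eta_squared=float(min(max(eta, 0.0), 1.0)),
        n_used=len(y),
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with pooled SD (no small-sample correction)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled == 0:
        return 0.0 if np.mean(a) == np.mean(b) else math.inf
    return float((np.mean(a) - np.mean(b)) / math.sqrt(pooled))


def tukey_posthoc_effects(values: Sequence[float], groups: Sequence[str]) -> list[PostHoc]:
    """All-pairs Tukey-Kramer tests (studentized range, unequal-n SE) + Cohen's d."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    mask = np.isfinite(y)
    y, g = y[mask], g[mask]
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {lab: y[g == lab] for lab in labels}
    ns = {lab: len(v) for lab, v in data.items()}
    df_error = sum(ns.values()) - len(labels)
    mse = sum(float(np.sum((v - v.mean()) ** 2)) for v in data.values()) / df_error
    out: list[PostHoc] = []
    for a, b in itertools.combinations(labels, 2):
        if ns[a] < 2 or ns[b] < 2:
            out.append(PostHoc(pair=(a, b), p_value=math.nan, cohens_d=math.nan, mean_diff=math.nan))
            continue
        diff = float(data[a].mean() - data[b].mean())
        se = math.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, len(labels), df_error))
        out.append(PostHoc(pair=(a, b), p_value=p, cohens_d=cohens_d(data[a], data[b]), mean_diff=diff))
    return out


def compare_groups(
    frame: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    covariate_col: Optional[str] = "education",
    fence_k: float = 3.0,
    fence_scope: str = "pooled",
) -> GroupComparison:
    """Outlier fencing + ANCOVA + post hocs for one feature column.

    ``fence_scope`` "pooled" fences on the pooled sample (default);
    "per_group" fences within each group separately.
    """
    sub = frame[[feature, group_col] + ([covariate_col] if covariate_col else [])].dropna()
    if fence_scope == "pooled":
        _, removed = remove_outliers(sub[feature].to_numpy(), k=fence_k)
        keep_mask = np.ones(len(sub), dtype=bool)
        keep_mask[removed] = False
    elif fence_scope == "per_group":
        keep_mask = np.ones(len(sub), dtype=bool)
        for _, idx in sub.groupby(group_col).indices.items():
            _, removed = remove_outliers(sub[feature].to_numpy()[idx], k=fence_k)
            keep_mask[np.asarray(idx)[removed]] = False
    else:
        raise ValueError("fence_scope must be 'pooled' or 'per_group'")
    n_removed = int((~keep_mask).sum())
    if n_removed:
        dropped = sub.loc[~keep_mask]
        for _, row in dropped.iterrows():
            logger.info("outlier removed: feature=%s participant_row=%s value=%g",
                        feature, row.name, row[feature])
    kept = sub.loc[keep_mask]
    result = ancova_oneway(
        kept[feature],
        kept[group_col],
        kept[covariate_col] if covariate_col else None,
        feature=feature,
    )
    result.n_outliers_removed = n_removed
    result.posthoc = tukey_posthoc_effects(kept[feature], kept[group_col])
    return result


def _residualize(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(cov)), cov])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def correlate_clinical(
    feature_values: Sequence[float],
    clinical_scores: Sequence[float],
    tandem: str = "",
    feature: str = "",
    clinical: str = "",
    covariate: Optional[Sequence[float]] = None,
    covariate_name: Optional[str] = None,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Distribution-gated correlation between a feature and a clinical score.

    Both variables are tested for normality (Shapiro-Wilk at ``alpha``);
    Pearson if both pass, Spearman otherwise.  With a covariate, both
    variables are residualized on it first (after rank transformation
    for Spearman), giving a partial correlation.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(clinical_scores, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    cov = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        mask &= np.isfinite(cov)
        cov = cov[mask]
    x, y = x[mask], y[mask]
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables; correlation undefined")
    normal = sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    method = "pearson" if normal else "spearman"
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        if cov is not None:
            cov = sps.rankdata(cov)
    if cov is not None:
        x = _residualize(x, cov)
        y = _residualize(y, cov)
        r, p = sps.pearsonr(x, y)
        # classic partial-correlation dof adjustment (one covariate)
        n = len(x)
        if abs(r) < 1:
            t = r * math.sqrt((n - 3) / (1 - r * r))
            p = float(2 * sps.t.sf(abs(t), n - 3))
    else:
        r, p = (sps.pearsonr(x, y) if method == "pearson" else sps.spearmanr(x, y))
        r, p = float(r), float(p)
    return CorrelationResult(
        feature=feature,
        clinical_score=clinical,
        tandem=tandem,
        method=method,
        coefficient=float(r),
        p_value=float(p),
        n=len(x),
        covariate=covariate_name,
    )
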