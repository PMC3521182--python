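"""Univariate feature selection by two-sample tests.

Genes are scored for class association with either the classic pooled-variance
two-sample t test (parametric) or the Wilcoxon rank-sum test (nonparametric),
and the top-k genes by ascending p-value are selected.  Scoring uses training
samples only.

The rank-sum p-value uses the normal approximation with tie and continuity
corrections, which keeps per-gene scoring cheap when selection is re-run per
bootstrap bag; an exact permutation-null cross-check lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LabeledDataset

__all__ = [
    "FeatureScore",
    "FeatureSelection",
    "t_statistic",
    "wilcoxon_rank_sum",
    "select_top_features",
    "SELECTORS",
]

SELECTORS = ("ttest", "wilcoxon")


@dataclass(frozen=True)
class FeatureScore:
    feature_id: str
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class FeatureSelection:
    """Top-k feature choice, ordered by ascending p-value.

    Ties in p-value are broken by descending |statistic|, then by feature ID,
    so the selected set is deterministic.
    """

    method: str
    k: int
    selected: tuple[str, ...]
    table: pd.DataFrame  # feature_id-indexed: statistic, p_value, selected


def t_statistic(pos, neg, *, feature_id: str = "", welch: bool = False) -> FeatureScore:
    """Two-sample t test for one gene (pooled-variance by default).

    Zero pooled variance is flagged degenerate with p = 1: a gene that is
    constant across all samples carries no class information.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("t test requires at least 2 samples per group")
    t, p = stats.ttest_ind(pos, neg, equal_var=not welch)
    if not np.isfinite(t):
        return FeatureScore(feature_id, 0.0, 1.0, degenerate=True)
    return FeatureScore(feature_id, float(t), float(p))


def wilcoxon_rank_sum(pos, neg, *, feature_id: str = "") -> FeatureScore:
    """Wilcoxon rank-sum test for one gene.

    The statistic is W, the rank sum of the positive group on the pooled
    average-tie ranks; the two-sided p-value uses the normal approximation
    with tie and continuity corrections.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("rank-sum test requires non-empty groups")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    w = float(ranks[: pos.size].sum())
    stat_, p = _ranksum_p(np.array([w]), pos.size, neg.size, np.array([stats.tiecorrect(ranks)]))
    return FeatureScore(feature_id, w, float(p[0]), degenerate=bool(stat_[0]))


def _ranksum_p(w: np.ndarray, n1: int, n2: int, tie_factor: np.ndarray):
    """Two-sided normal-approximation p for rank sums ``w`` of the size-n1 group.

    Returns (degenerate mask, p values).  ``tie_factor`` is scipy's tie
    correction factor per gene (0 when every pooled value is tied).
    """
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    sigma = np.sqrt(tie_factor * n1 * n2 * (n + 1) / 12.0)
    degenerate = sigma == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = w - mu
        z = (d - 0.5 * np.sign(d)) / sigma  # continuity correction
    p = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return degenerate, np.minimum(p, 1.0)


def _score_all(X: np.ndarray, is_pos: np.ndarray, method: str):
    """Vectorised scoring of every gene (row of X). Returns (stat, p, degenerate)."""
    Xp, Xn = X[:, is_pos], X[:, ~is_pos]
    if method == "ttest":
        if Xp.shape[1] < 2 or Xn.shape[1] < 2:
            raise ValueError("t test requires at least 2 samples per group")
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(Xp, Xn, axis=1)
        degenerate = ~np.isfinite(t)
        return np.where(degenerate, 0.0, t), np.where(degenerate, 1.0, p), degenerate
    if method == "wilcoxon":
        ranks = stats.rankdata(X, method="average", axis=1)
        w = ranks[:, is_pos].sum(axis=1)
        tie = np.array([stats.tiecorrect(r) for r in ranks])
        degenerate, p = _ranksum_p(w, int(is_pos.sum()), int((~is_pos).sum()), tie)
        return w, p, degenerate
    raise ValueError(f"unknown selection method {method!r}; expected one of {SELECTORS}")


def select_top_features(data: LabeledDataset, method: str, k: int) -> FeatureSelection:
    """Score every gene on the training data and return the top-k by p-value."""
    if k < 1:
        raise ValueError("k must be >= 1")
    data.require_both_classes()
    X = data.matrix.to_numpy(dtype=float)
    stat, p, degenerate = _score_all(X, data.labels.to_numpy(), method)
    table = pd.DataFrame(
        {"statistic": stat, "p_value": p, "degenerate": degenerate},
        index=data.matrix.index.astype(str),
    )
    order = table.assign(_negabs=-table.statistic.abs(), _fid=table.index).sort_values(
        ["p_value", "_negabs", "_fid"], kind="mergesort"
    )
    chosen = tuple(order.index[: min(k, len(order))])
    table["selected"] = table.index.isin(chosen)
    return FeatureSelection(method=method, k=k, selected=chosen, table=table)
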