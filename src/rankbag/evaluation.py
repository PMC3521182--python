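"""AUC evaluation and the cross-batch scenario grid.

A scenario cell is one combination of (dataset, prediction direction,
feature selector, base classifier, training-subset fraction, method arm).
Forward prediction trains on the training batch and evaluates on the test
batch; backward swaps them.  The method arms are:

* ``baseline_absolute`` — absolute values, single classifier, no bagging
  (the "before" arm every change is measured against),
* ``rank`` — rank values, single classifier,
* ``bag10`` / ``bag100`` — rank values, fixed-size bagging,
* ``dynamic`` — rank values, dynamic bagging (ensemble sized per instance).

AUC is the Mann–Whitney probability that a random positive outscores a random
negative, with ties counted half; changes are categorised by the ±0.05
thresholds: Increased (> 0.05), IncreasedSlightly (0 ≤ Δ ≤ 0.05),
DecreasedSlightly (−0.05 ≤ Δ < 0), Decreased (< −0.05).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .bagging import SequentialTestConfig, fixed_bagging, predict_dataset
from .io import LabeledDataset
from .ranking import rank_matrix
from .selection import select_top_features

__all__ = [
    "ARMS",
    "CATEGORIES",
    "ScenarioConfig",
    "ScenarioResult",
    "auc",
    "auc_change_category",
    "subsample_stratified",
    "run_scenario",
    "run_grid",
    "summarize_categories",
]

ARMS = ("baseline_absolute", "rank", "bag10", "bag100", "dynamic")
CATEGORIES = ("Increased", "IncreasedSlightly", "DecreasedSlightly", "Decreased")


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney formulation, ties count half)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_change_category(before: float, after: float) -> str:
    """Categorise an AUC change by the ±0.05 thresholds (boundaries inclusive
    toward the 'slightly' categories)."""
    for v in (before, after):
        if not 0.0 <= v <= 1.0:
            raise ValueError("AUC values must lie in [0, 1]")
    # snap away float representation error so exact ±0.05 changes land in the
    # inclusive 'slightly' categories
    change = round(after - before, 12)
    if change > 0.05:
        return "Increased"
    if change >= 0.0:
        return "IncreasedSlightly"
    if change >= -0.05:
        return "DecreasedSlightly"
    return "Decreased"


def subsample_stratified(
    data: LabeledDataset, fraction: float, rng: np.random.Generator
) -> LabeledDataset:
    """Random per-class subsample without replacement, preserving class ratio.

    Per-class counts are round(fraction × class size), at least 1.  With
    fraction = 1.0 the dataset is returned unchanged (order preserved).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return data
    y = data.labels.to_numpy()
    keep: list[int] = []
    for cls in (True, False):
        idx = np.where(y == cls)[0]
        if len(idx) == 0:
            raise ValueError("cannot subsample: a class is absent")
        n_keep = max(1, round(fraction * len(idx)))
        keep.extend(rng.choice(idx, size=n_keep, replace=False))
    keep = sorted(keep)
    cols = data.matrix.columns[keep]
    return LabeledDataset(data.matrix[cols], data.labels[cols])


@dataclass(frozen=True)
class ScenarioConfig:
    selector: str = "ttest"
    classifier: str = "svm"
    k: int = 100
    arm: str = "dynamic"
    sprt: SequentialTestConfig = field(default_factory=SequentialTestConfig)
    seed: int = 0
    rank_before_selection: bool = True  # ranks computed on the full feature set

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")


@dataclass(frozen=True)
class ScenarioResult:
    dataset_id: str
    direction: str
    selector: str
    classifier: str
    subset_fraction: float
    arm: str
    auc_before: float
    auc_after: float
    category: str
    n_used_min: int
    n_used_max: int
    n_used_mean: float


def _arm_predictions(
    train: LabeledDataset, test: pd.DataFrame, cfg: ScenarioConfig, arm: str
):
    use_ranks = arm != "baseline_absolute"
    if use_ranks:
        # rank on the full feature set first: a test instance's representation
        # must not depend on which features this training run selected
        train = LabeledDataset(rank_matrix(train.matrix), train.labels)
        test = rank_matrix(test)
    k = min(cfg.k, train.n_features)
    features = select_top_features(train, cfg.selector, k)
    if arm in ("baseline_absolute", "rank"):
        return fixed_bagging(train, test, cfg.classifier, features, 1, cfg.seed, bootstrap=False)
    if arm == "bag10":
        return fixed_bagging(train, test, cfg.classifier, features, 10, cfg.seed)
    if arm == "bag100":
        return fixed_bagging(train, test, cfg.classifier, features, 100, cfg.seed)
    return predict_dataset(train, test, cfg.classifier, features, cfg.sprt, cfg.seed)


def run_scenario(
    train: LabeledDataset,
    test: LabeledDataset,
    cfg: ScenarioConfig,
    *,
    dataset_id: str = "dataset",
    direction: str = "forward",
    subset_fraction: float = 1.0,
) -> ScenarioResult:
    """Execute one scenario cell: the baseline-absolute arm plus ``cfg.arm``.

    Returns the before/after AUCs and the change category; n_used summaries
    describe the ensemble sizes of the (bagging) arm across test instances.
    """
    train.require_both_classes()
    base = _arm_predictions(train, test.matrix, cfg, "baseline_absolute")
    auc_before = auc([r.score for r in base], test.labels)
    if cfg.arm == "baseline_absolute":
        after, auc_after = base, auc_before
    else:
        after = _arm_predictions(train, test.matrix, cfg, cfg.arm)
        auc_after = auc([r.score for r in after], test.labels)
    n_used = [r.n_used for r in after]
    return ScenarioResult(
        dataset_id=dataset_id,
        direction=direction,
        selector=cfg.selector,
        classifier=cfg.classifier,
        subset_fraction=subset_fraction,
        arm=cfg.arm,
        auc_before=auc_before,
        auc_after=auc_after,
        category=auc_change_category(auc_before, auc_after),
        n_used_min=int(min(n_used)),
        n_used_max=int(max(n_used)),
        n_used_mean=float(np.mean(n_used)),
    )


def _cell_seed(master_seed: int, *parts) -> int:
    key = "|".join(str(p) for p in parts)
    return (int(master_seed) ^ zlib.crc32(key.encode())) & 0x7FFFFFFF


def run_grid(
    datasets: dict[str, tuple[LabeledDataset, LabeledDataset]],
    *,
    arms=("dynamic",),
    selectors=("ttest", "wilcoxon"),
    classifiers=("svm", "knn", "tree"),
    subset_fractions=(1.0,),
    k: int = 100,
    sprt: SequentialTestConfig | None = None,
    master_seed: int = 0,
    negative_controls: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Run the full scenario cross-product and return a long-format table.

    Per subset fraction the grid has |datasets| × 2 directions × |selectors| ×
    |classifiers| cells per arm.  Subsampling applies to the training batch of
    the cell only.  Cells for datasets named in ``negative_controls`` are
    flagged so improvement statistics can exclude them.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    sprt = sprt or SequentialTestConfig()
    rows = []
    for name, (tr, te) in datasets.items():
        for direction, frac, sel, clf, arm in itertools.product(
            ("forward", "backward"), subset_fractions, selectors, classifiers, arms
        ):
            train, test = (tr, te) if direction == "forward" else (te, tr)
            seed = _cell_seed(master_seed, name, direction, frac, sel, clf)
            sub_rng = np.random.default_rng(_cell_seed(master_seed, "subsample", name, direction, frac))
            train_sub = subsample_stratified(train, frac, sub_rng)
            cfg = ScenarioConfig(selector=sel, classifier=clf, k=k, arm=arm, sprt=sprt, seed=seed)
            res = run_scenario(
                train_sub, test, cfg,
                dataset_id=name, direction=direction, subset_fraction=frac,
            )
            row = res.__dict__.copy()
            row["negative_control"] = name in negative_controls
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_categories(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-arm AUC-change category percentages, excluding negative controls."""
    sub = grid[~grid["negative_control"]]
    out = []
    for arm, g in sub.groupby("arm"):
        counts = g["category"].value_counts()
        row = {"arm": arm, "cells": len(g)}
        for cat in CATEGORIES:
            row[cat] = 100.0 * counts.get(cat, 0) / len(g)
        out.append(row)
    return pd.DataFrame(out)
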