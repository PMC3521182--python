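"""Synthetic two-batch expression data with controllable batch effects.

The generator emulates the structure the rank + bagging method assumes about
cross-batch microarray prediction:

* a log2-scale expression matrix with heterogeneous per-gene baselines,
* a subset of class-informative genes whose means differ between classes,
* a test batch whose values are distorted by per-sample strictly monotone
  maps (affine shift/scale with per-sample jitter, optionally composed with a
  cube, exp or random piecewise-linear warp) — the regime in which batch
  effects move absolute values but preserve each sample's gene ordering,
* a minority fraction of "bad" training samples (label flips, or extreme
  noise in the alternative mode),
* a negative-control mode with random labels and no class signal.

Severity presets (low / medium / high) loosely mirror the ordering of batch
effects the source cohorts display under PCA: "low" is a mild affine shift,
"high" adds a strongly nonlinear (exp) per-sample warp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .io import LabeledDataset

__all__ = ["SyntheticConfig", "generate", "emulate_paper_sizes", "severity_preset"]

Distortion = Literal["none", "cube", "exp", "random_piecewise"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic two-batch dataset.

    effect_size is the per-informative-gene mean shift in units of that gene's
    baseline standard deviation (a per-gene Cohen's d); batch_shift_additive
    and batch_scale_multiplicative are the centres of the per-sample affine
    distortion of the test batch; bad_fraction is the fraction of training
    labels flipped (must stay below 1/2 — the minority-contamination regime
    the enrichment theory requires).
    """

    n_genes: int = 500
    n_informative: int = 30
    effect_size: float = 1.0
    n_train: int = 60
    n_test: int = 60
    class_ratio: float = 0.4
    test_class_ratio: float | None = None
    batch_shift_additive: float = 1.0
    batch_scale_multiplicative: float = 1.3
    monotone_distortion: Distortion = "none"
    bad_fraction: float = 0.0
    bad_mode: Literal["flip", "noise"] = "flip"
    noise_sd: float = 1.0
    negative_control: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bad_fraction < 0.5:
            raise ValueError("bad_fraction must be in [0, 0.5)")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        for r in (self.class_ratio, self.test_class_ratio):
            if r is not None and not 0.0 < r < 1.0:
                raise ValueError("class ratios must be in (0, 1)")
        if min(self.n_train, self.n_test) < 4:
            raise ValueError("need at least 4 samples per batch")
        if self.batch_scale_multiplicative <= 0:
            raise ValueError("multiplicative scale must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


_SEVERITY = {
    "low": dict(batch_shift_additive=0.5, batch_scale_multiplicative=1.1, monotone_distortion="none"),
    "medium": dict(batch_shift_additive=1.0, batch_scale_multiplicative=1.3, monotone_distortion="cube"),
    "high": dict(batch_shift_additive=2.0, batch_scale_multiplicative=1.5, monotone_distortion="exp"),
}


def severity_preset(config: SyntheticConfig, severity: str) -> SyntheticConfig:
    """Return a copy of ``config`` with the batch-effect fields of a preset."""
    if severity not in _SEVERITY:
        raise ValueError(f"unknown severity {severity!r}; expected one of {sorted(_SEVERITY)}")
    return replace(config, **_SEVERITY[severity])


def _labels(n: int, ratio: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = max(1, min(n - 1, round(ratio * n)))
    y = np.zeros(n, dtype=bool)
    y[rng.choice(n, size=n_pos, replace=False)] = True
    return y


def _monotone_warp(values: np.ndarray, kind: Distortion, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing per-sample warp of a (genes,) value vector."""
    if kind == "none":
        return values
    if kind == "cube":
        c = values.mean()
        return ((values - c) / 3.0) ** 3 + values  # x + ((x-c)/3)^3: strictly increasing
    if kind == "exp":
        return np.exp(values / 3.0)
    if kind == "random_piecewise":
        # random increasing piecewise-linear map over the sample's value range
        lo, hi = values.min(), values.max()
        knots_x = np.linspace(lo, hi, 6)
        gaps = rng.uniform(0.2, 2.0, size=5)
        knots_y = lo + (hi - lo) * np.concatenate([[0.0], np.cumsum(gaps)]) / gaps.sum()
        return np.interp(values, knots_x, knots_y)
    raise ValueError(f"unknown distortion {kind!r}")


def _distort_batch(X: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the per-sample batch distortion to a (genes × samples) matrix."""
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        # per-sample affine jitter around the configured centres (sd = 20%)
        a = rng.normal(cfg.batch_shift_additive, 0.2 * abs(cfg.batch_shift_additive) + 1e-12)
        b = cfg.batch_scale_multiplicative * np.exp(rng.normal(0.0, 0.1))
        out[:, j] = a + b * _monotone_warp(X[:, j], cfg.monotone_distortion, rng)
    return out


def generate(config: SyntheticConfig) -> tuple[LabeledDataset, LabeledDataset, dict]:
    """Generate (train, test, truth) for one two-batch synthetic dataset.

    ``truth`` records the informative gene IDs, the IDs of corrupted ("bad")
    training samples, and the config used.  The train batch is the undistorted
    reference frame; all batch distortion is applied to the test batch.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]
    mu = rng.normal(7.0, 1.5, size=G)          # log2-scale baselines
    sd = rng.uniform(0.5, 1.5, size=G) * config.noise_sd
    informative = np.sort(rng.choice(G, size=config.n_informative, replace=False))
    direction = rng.choice([-1.0, 1.0], size=config.n_informative)

    y_tr = _labels(config.n_train, config.class_ratio, rng)
    ratio_te = config.test_class_ratio if config.test_class_ratio is not None else config.class_ratio
    y_te = _labels(config.n_test, ratio_te, rng)

    def batch(y: np.ndarray, prefix: str) -> pd.DataFrame:
        n = len(y)
        X = mu[:, None] + sd[:, None] * rng.normal(size=(G, n))
        if not config.negative_control:
            shift = (config.effect_size * sd[informative] * direction)[:, None]
            X[np.ix_(informative, np.where(y)[0])] += shift
        return pd.DataFrame(X, index=gene_ids, columns=[f"{prefix}{j:04d}" for j in range(n)])

    Xtr = batch(y_tr, "tr")
    Xte = batch(y_te, "te")
    Xte.loc[:, :] = _distort_batch(Xte.to_numpy(), config, rng)

    # corrupt a minority of training samples
    y_tr_obs = y_tr.copy()
    n_bad = round(config.bad_fraction * config.n_train)
    bad_idx = np.sort(rng.choice(config.n_train, size=n_bad, replace=False)) if n_bad else np.array([], dtype=int)
    if config.bad_mode == "flip":
        y_tr_obs[bad_idx] = ~y_tr_obs[bad_idx]
    else:  # extreme-noise mode: keep labels, swamp the profiles
        Xtr.iloc[:, bad_idx] += rng.normal(0.0, 10.0 * config.noise_sd, size=(G, n_bad))

    if config.negative_control:
        # labels carry no information by construction; re-randomise for clarity
        y_tr_obs = _labels(config.n_train, config.class_ratio, rng)
        y_te = _labels(config.n_test, ratio_te, rng)

    train = LabeledDataset(Xtr, pd.Series(y_tr_obs, index=Xtr.columns))
    test = LabeledDataset(Xte, pd.Series(y_te, index=Xte.columns))
    truth = {
        "informative_genes": [gene_ids[i] for i in informative],
        "bad_samples": [Xtr.columns[i] for i in bad_idx],
        "config": config,
    }
    return train, test, truth


# Table of cohort sizes emulated from the source study's four MAQC data sets:
# (n_train, train positives, n_test, test positives, negative control)
_PAPER_SIZES = {
    "A": (70, 26, 88, 28, False),
    "D": (130, 33, 100, 15, False),
    "F": (340, 51, 214, 27, False),
    "I": (340, 200, 214, 122, True),
}


def emulate_paper_sizes(which: str) -> SyntheticConfig:
    """Configs matching the published cohort sizes and class ratios (A/D/F/I).

    Data set I is the negative control (random labels).  Batch-effect severity
    follows the cohorts' PCA ordering: A worst, D intermediate, F/I mildest.
    """
    if which not in _PAPER_SIZES:
        raise ValueError(f"unknown data set code {which!r}; expected one of {sorted(_PAPER_SIZES)}")
    n_tr, pos_tr, n_te, pos_te, negctl = _PAPER_SIZES[which]
    cfg = SyntheticConfig(
        n_genes=1000,
        n_train=n_tr,
        n_test=n_te,
        class_ratio=pos_tr / n_tr,
        test_class_ratio=pos_te / n_te,
        negative_control=negctl,
        bad_fraction=0.1,
    )
    severity = {"A": "high", "D": "medium", "F": "low", "I": "low"}[which]
    return severity_preset(cfg, severity)
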