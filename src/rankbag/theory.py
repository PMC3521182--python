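"""Clean-bag enrichment: why bootstrap bags favour good samples.

Suppose a training set S of m samples contains x "bad" samples (mislabelled or
extremely noisy) and y = m − x good ones, with bad fraction q = x/m and
p = 1 − q.  A bootstrap bag B of m samples drawn with replacement from S
contains k bad samples with binomial probability

    P_B(k) = C(m, k) p^(m−k) q^k.

When q < 1/2 the binomial is right-skewed about its mean mq = x, so a bag is
more likely to contain *fewer* bad samples than S than to contain more:
P_B(<x) > P_B(>x).  Over many bags, the fraction with fewer bad samples than S
(h/n), more (h′/n) and equally many (h″/n) converge to P_B(<x), P_B(>x) and
P_B(x).  This is the enrichment argument behind bagging on noisy training
sets: most bags are at least as clean as the data they came from, provided
bad samples are a minority.

The skewness is implemented in its standard form (1 − 2q)/√(mqp); only its
sign and zero-crossing at q = 1/2 enter the argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NoiseModel",
    "BagQualityFractions",
    "binomial_pmf",
    "enrichment_advantage",
    "binomial_skewness",
    "simulate_bag_quality",
]


@dataclass(frozen=True)
class NoiseModel:
    """Training-set contamination model: m samples of which x are bad."""

    m: int
    x: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 <= self.x <= self.m:
            raise ValueError(f"x must lie in [0, m={self.m}], got {self.x}")

    @property
    def q(self) -> float:
        """Bad-sample fraction x/m."""
        return self.x / self.m

    @property
    def p(self) -> float:
        """Good-sample fraction 1 − q."""
        return 1.0 - self.q


@dataclass(frozen=True)
class BagQualityFractions:
    """Monte-Carlo fractions of bags cleaner / dirtier / as dirty as S."""

    n: int
    h_frac: float           # fewer bad samples than S
    hprime_frac: float      # more bad samples than S
    hdoubleprime_frac: float  # exactly as many


def binomial_pmf(model: NoiseModel, k: int) -> float:
    """P_B(k): probability a bootstrap bag contains exactly k bad samples."""
    if not 0 <= k <= model.m:
        raise ValueError(f"k must lie in [0, m={model.m}], got {k}")
    # scipy computes the pmf in log space internally, so large m is safe
    return float(stats.binom.pmf(k, model.m, model.q))


def enrichment_advantage(model: NoiseModel) -> float:
    """P_B(<x) − P_B(>x): the bagging clean-sample advantage.

    Strictly positive whenever 0 < q < 1/2; zero when x = 0 (no bag can be
    cleaner, none dirtier with q = 0 — with q = 0 exactly 0).
    """
    below = float(stats.binom.cdf(model.x - 1, model.m, model.q)) if model.x > 0 else 0.0
    above = float(stats.binom.sf(model.x, model.m, model.q))
    return below - above


def binomial_skewness(model: NoiseModel) -> float:
    """Skewness (1 − 2q)/√(mqp) of the bag-contamination distribution."""
    if model.x == 0 or model.x == model.m:
        raise ValueError("skewness is undefined for q in {0, 1}")
    return (1.0 - 2.0 * model.q) / np.sqrt(model.m * model.q * model.p)


def simulate_bag_quality(
    model: NoiseModel, n: int, rng: np.random.Generator
) -> BagQualityFractions:
    """Draw n bootstrap bags by explicit index resampling and classify each.

    Serves as the simulation oracle for the closed-form tails: h/n → P_B(<x)
    etc. as n → ∞.  Bags are drawn as actual index multisets (not by sampling
    the binomial directly) so the simulation is independent of the closed form
    it validates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fewer = more = equal = 0
    chunk = max(1, 2_000_000 // model.m)
    remaining = n
    while remaining > 0:
        c = min(chunk, remaining)
        idx = rng.integers(0, model.m, size=(c, model.m))
        bad_counts = (idx < model.x).sum(axis=1)  # samples 0..x-1 are the bad ones
        fewer += int((bad_counts < model.x).sum())
        more += int((bad_counts > model.x).sum())
        equal += int((bad_counts == model.x).sum())
        remaining -= c
    return BagQualityFractions(n, fewer / n, more / n, equal / n)
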