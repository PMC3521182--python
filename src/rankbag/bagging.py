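"""Dynamic bagging: bootstrap ensembles sized per test instance by an SPRT.

For each test instance, bootstrap bags of m training samples are drawn with
replacement, a base classifier is trained on each bag, and its Boolean vote on
the instance feeds a Wald sequential probability ratio test of

    H0: Pr(vote = True) <= theta - delta   vs   H1: Pr(vote = True) >= theta + delta

with theta = 0.5 by default: "would a majority of bootstrap classifiers call
this instance positive?".  Voting stops as soon as the accumulated
log-likelihood ratio crosses a Wald boundary — log((1-beta)/alpha) above,
log(beta/(1-alpha)) below — which guarantees false-positive rate <= alpha and
false-negative rate <= beta for vote probabilities outside the indifference
region (theta-delta, theta+delta).  A cap n_max bounds the ensemble; at the
cap with no decision the majority vote decides, ties going negative.

The reported prediction score is the arithmetic mean of the member
classifiers' probability scores, so downstream AUC uses graded scores rather
than the Boolean decision.

Per-instance randomness is seeded from (master seed, sample ID), so each test
instance's result is independent of the composition and order of the rest of
the test set.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import LabeledDataset
from .selection import FeatureSelection

__all__ = [
    "SequentialTestConfig",
    "SequentialTestState",
    "PredictionResult",
    "CLASSIFIERS",
    "draw_bag",
    "sprt_update",
    "predict_instance",
    "predict_dataset",
    "fixed_bagging",
    "simulate_vote_streams",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm", "knn", "tree")

_MAX_BAG_RETRIES = 1000


@dataclass(frozen=True)
class SequentialTestConfig:
    """Parameters of the sequential vote test.

    theta   : vote-probability threshold (0.5 = majority).
    alpha   : guaranteed false-positive rate of the test.
    beta    : guaranteed false-negative rate.
    delta   : half-width of the indifference region around theta.
    n_max   : hard cap on classifiers per instance.
    n_min   : minimum votes before any decision.
    """

    theta: float = 0.5
    alpha: float = 1e-4
    beta: float = 1e-4
    delta: float = 0.1
    n_max: int = 100
    n_min: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if not 0.0 < self.delta < min(self.theta, 1.0 - self.theta):
            raise ValueError("delta must be in (0, min(theta, 1-theta))")
        if not (0.0 < self.alpha < 0.5 and 0.0 < self.beta < 0.5):
            raise ValueError("alpha and beta must be in (0, 0.5)")
        if not self.n_max >= self.n_min >= 1:
            raise ValueError("need n_max >= n_min >= 1")

    @property
    def log_upper(self) -> float:
        """Accept-H1 boundary log((1-beta)/alpha)."""
        return math.log((1.0 - self.beta) / self.alpha)

    @property
    def log_lower(self) -> float:
        """Accept-H0 boundary log(beta/(1-alpha))."""
        return math.log(self.beta / (1.0 - self.alpha))

    def increment(self, vote: bool) -> float:
        """Log-likelihood-ratio step for one Boolean vote."""
        p1, p0 = self.theta + self.delta, self.theta - self.delta
        if vote:
            return math.log(p1 / p0)
        return math.log((1.0 - p1) / (1.0 - p0))


@dataclass(frozen=True)
class SequentialTestState:
    votes_seen: int = 0
    positives: int = 0
    log_lr: float = 0.0
    status: str = "continue"  # continue | accept_H1 | accept_H0 | capped


@dataclass(frozen=True)
class PredictionResult:
    """Outcome for one test instance.

    score is the exact arithmetic mean of the n_used member scores.
    stop_reason: sprt_accept | sprt_reject | cap | fixed.
    """

    sample_id: str
    score: float
    decision: bool
    n_used: int
    stop_reason: str
    votes_positive: int = 0


def sprt_update(
    state: SequentialTestState, vote: bool, cfg: SequentialTestConfig
) -> SequentialTestState:
    """Fold one Boolean vote into the sequential test and re-evaluate stopping."""
    if state.status != "continue":
        raise ValueError(f"sequential test already terminal ({state.status})")
    n = state.votes_seen + 1
    pos = state.positives + int(vote)
    llr = state.log_lr + cfg.increment(vote)
    status = "continue"
    if n >= cfg.n_min:
        if llr >= cfg.log_upper:
            status = "accept_H1"
        elif llr <= cfg.log_lower:
            status = "accept_H0"
    if status == "continue" and n >= cfg.n_max:
        status = "capped"
    return SequentialTestState(votes_seen=n, positives=pos, log_lr=llr, status=status)


def simulate_vote_streams(
    p_true: float,
    cfg: SequentialTestConfig,
    n_streams: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo the sequential test on i.i.d. Bernoulli(p_true) vote streams.

    Returns (decisions, votes_used): the Boolean decision and the number of
    votes consumed for each stream, applying exactly the stopping rule of
    :func:`sprt_update` (Wald boundaries, n_min, cap with majority/tie→negative),
    vectorised so error-guarantee checks at 10^5+ streams are cheap.  Agreement
    with the scalar update path is asserted in the test suite.
    """
    up, lo = cfg.log_upper, cfg.log_lower
    inc_t, inc_f = cfg.increment(True), cfg.increment(False)
    decisions = np.empty(n_streams, dtype=bool)
    used = np.empty(n_streams, dtype=np.int64)
    chunk = max(1, 20_000_000 // cfg.n_max)
    done = 0
    while done < n_streams:
        c = min(chunk, n_streams - done)
        votes = rng.random((c, cfg.n_max)) < p_true
        llr = np.cumsum(np.where(votes, inc_t, inc_f), axis=1)
        hit_up = llr >= up
        hit_lo = llr <= lo
        if cfg.n_min > 1:  # no decision before n_min votes
            hit_up[:, : cfg.n_min - 1] = False
            hit_lo[:, : cfg.n_min - 1] = False
        crossing = hit_up | hit_lo
        any_cross = crossing.any(axis=1)
        first = np.where(any_cross, crossing.argmax(axis=1), cfg.n_max - 1)
        rows = np.arange(c)
        dec = np.where(any_cross, hit_up[rows, first], np.nan)
        # capped streams: strict majority of all n_max votes, ties -> negative
        capped = ~any_cross
        if capped.any():
            pos = votes[capped].sum(axis=1)
            dec[capped] = pos * 2 > cfg.n_max
        decisions[done : done + c] = dec.astype(bool)
        used[done : done + c] = first + 1
        done += c
    return decisions, used


def _decision_from_state(state: SequentialTestState) -> tuple[bool, str]:
    if state.status == "accept_H1":
        return True, "sprt_accept"
    if state.status == "accept_H0":
        return False, "sprt_reject"
    # capped: strict majority of votes; ties -> negative
    return state.positives * 2 > state.votes_seen, "cap"


# ---------------------------------------------------------------------------
# base classifiers


class _SvmScorer:
    """Linear-kernel SVM with a logistic squash of the decision margin.

    predict(score >= 0.5) coincides exactly with the sign of the margin.
    """

    def fit(self, X, y):
        self._clf = SVC(kernel="linear", C=1.0)
        self._clf.fit(X, y)
        return self

    def score_samples(self, X) -> np.ndarray:
        return expit(self._clf.decision_function(X))


class _KnnScorer:
    """k-nearest-neighbour vote fraction (K = 5, reduced for tiny bags)."""

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        self._clf = KNeighborsClassifier(n_neighbors=min(self.k, len(X)))
        self._clf.fit(X, y)
        return self

    def score_samples(self, X) -> np.ndarray:
        proba = self._clf.predict_proba(X)
        return proba[:, list(self._clf.classes_).index(True)]


class _TreeScorer:
    """Decision tree scored by Laplace-smoothed leaf class frequencies.

    Smoothing (n_pos+1)/(n+2) keeps scores off the hard 0/1 endpoints so the
    ensemble mean stays informative for AUC.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, X, y):
        self._clf = DecisionTreeClassifier(random_state=self.random_state)
        self._clf.fit(X, y)
        return self

    def score_samples(self, X) -> np.ndarray:
        leaves = self._clf.apply(X)
        counts = self._clf.tree_.value[leaves][:, 0, :] * self._clf.tree_.n_node_samples[leaves][:, None]
        pos_col = list(self._clf.classes_).index(True)
        n_pos = counts[:, pos_col]
        n_tot = counts.sum(axis=1)
        return (n_pos + 1.0) / (n_tot + 2.0)


def _make_scorer(classifier: str, rng: np.random.Generator):
    if classifier == "svm":
        return _SvmScorer()
    if classifier == "knn":
        return _KnnScorer()
    if classifier == "tree":
        return _TreeScorer(random_state=int(rng.integers(0, 2**31 - 1)))
    raise ValueError(f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}")


# ---------------------------------------------------------------------------
# bagging


def _draw_bag_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """m uniform draws with replacement; single-class bags are redrawn."""
    m = len(y)
    for _ in range(_MAX_BAG_RETRIES):
        idx = rng.integers(0, m, size=m)
        picked = y[idx]
        if picked.any() and not picked.all():
            return idx
        logger.debug("redrawing single-class bag")
    raise RuntimeError(
        f"failed to draw a two-class bag in {_MAX_BAG_RETRIES} tries; "
        "class ratio is pathological — consider a stratified draw"
    )


def draw_bag(train: LabeledDataset, rng: np.random.Generator) -> np.ndarray:
    """Draw one bootstrap bag (array of m sample indices) from the training set."""
    if train.n_samples < 2:
        raise ValueError("bootstrap bags need at least 2 training samples")
    train.require_both_classes()
    return _draw_bag_indices(train.labels.to_numpy(), rng)


def _train_matrix(train: LabeledDataset, features: FeatureSelection | None):
    mat = train.matrix if features is None else train.matrix.loc[list(features.selected)]
    return mat.to_numpy(dtype=float).T, train.labels.to_numpy()


def _instance_vector(instance: pd.Series, features: FeatureSelection | None) -> np.ndarray:
    vec = instance if features is None else instance.loc[list(features.selected)]
    return np.asarray(vec, dtype=float)[None, :]


def _predict_one(
    X: np.ndarray,
    y: np.ndarray,
    xi: np.ndarray,
    classifier: str,
    cfg: SequentialTestConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> PredictionResult:
    state = SequentialTestState()
    scores: list[float] = []
    failures = 0
    while state.status == "continue":
        idx = _draw_bag_indices(y, rng)
        try:
            scorer = _make_scorer(classifier, rng).fit(X[idx], y[idx])
            s = float(scorer.score_samples(xi)[0])
        except Exception:
            failures += 1
            logger.warning("bag training failed for %s (%d consecutive)", sample_id, failures)
            if failures > cfg.n_max:
                raise RuntimeError(
                    f"more than {cfg.n_max} consecutive bag-training failures for {sample_id}"
                )
            continue
        failures = 0
        scores.append(s)
        state = sprt_update(state, s >= 0.5, cfg)
    decision, reason = _decision_from_state(state)
    return PredictionResult(
        sample_id=sample_id,
        score=float(np.mean(scores)),
        decision=decision,
        n_used=len(scores),
        stop_reason=reason,
        votes_positive=state.positives,
    )


def _instance_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    # seed depends only on (master seed, sample id): results are independent
    # of test-set composition and order
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])
    )


def predict_instance(
    train: LabeledDataset,
    instance: pd.Series,
    classifier: str,
    features: FeatureSelection | None,
    cfg: SequentialTestConfig,
    rng: np.random.Generator,
    *,
    sample_id: str = "",
) -> PredictionResult:
    """Dynamically bagged prediction for one (already rank-transformed) instance."""
    train.require_both_classes()
    X, y = _train_matrix(train, features)
    xi = _instance_vector(instance, features)
    return _predict_one(X, y, xi, classifier, cfg, rng, sample_id)


def predict_dataset(
    train: LabeledDataset,
    test: pd.DataFrame,
    classifier: str,
    features: FeatureSelection | None,
    cfg: SequentialTestConfig,
    master_seed: int,
) -> list[PredictionResult]:
    """Independent per-instance dynamic bagging over every test sample (column)."""
    train.require_both_classes()
    X, y = _train_matrix(train, features)
    sel = list(features.selected) if features is not None else list(train.matrix.index)
    test_sel = test.loc[sel]
    results = []
    for sid in test.columns:
        xi = test_sel[sid].to_numpy(dtype=float)[None, :]
        rng = _instance_rng(master_seed, str(sid))
        results.append(_predict_one(X, y, xi, classifier, cfg, rng, str(sid)))
    return results


def fixed_bagging(
    train: LabeledDataset,
    test: pd.DataFrame,
    classifier: str,
    features: FeatureSelection | None,
    n_bags: int,
    master_seed: int,
    *,
    bootstrap: bool = True,
) -> list[PredictionResult]:
    """Classic bagging with a fixed ensemble size.

    One shared ensemble of n_bags classifiers is trained from the seeded bag
    stream and applied to every test instance.  With ``bootstrap=False`` and
    n_bags=1 the single classifier is trained on the whole training set — the
    no-bagging baseline.
    """
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    train.require_both_classes()
    X, y = _train_matrix(train, features)
    rng = np.random.default_rng(int(master_seed) & 0x7FFFFFFF)
    scorers = []
    for _ in range(n_bags):
        idx = _draw_bag_indices(y, rng) if bootstrap else np.arange(len(y))
        scorers.append(_make_scorer(classifier, rng).fit(X[idx], y[idx]))
    sel = list(features.selected) if features is not None else list(train.matrix.index)
    Xt = test.loc[sel].to_numpy(dtype=float).T
    member_scores = np.column_stack([s.score_samples(Xt) for s in scorers])
    mean_scores = member_scores.mean(axis=1)
    votes = (member_scores >= 0.5).sum(axis=1)
    return [
        PredictionResult(
            sample_id=str(sid),
            score=float(mean_scores[i]),
            decision=bool(votes[i] * 2 > n_bags),
            n_used=n_bags,
            stop_reason="fixed",
            votes_positive=int(votes[i]),
        )
        for i, sid in enumerate(test.columns)
    ]
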