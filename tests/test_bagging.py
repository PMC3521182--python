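import math

import numpy as np
import pandas as pd
import pytest

from rankbag.bagging import (
    PredictionResult,
    SequentialTestConfig,
    SequentialTestState,
    draw_bag,
    fixed_bagging,
    predict_dataset,
    predict_instance,
    simulate_vote_streams,
    sprt_update,
)
from rankbag.io import LabeledDataset
from rankbag.selection import select_top_features
from rankbag.theory import NoiseModel, enrichment_advantage

from conftest import make_dataset


def run_stream(votes, cfg):
    state = SequentialTestState()
    for v in votes:
        state = sprt_update(state, v, cfg)
        if state.status != "continue":
            break
    return state


class TestSprt:
    def test_wald_boundary_arithmetic(self):
        cfg = SequentialTestConfig()
        assert cfg.increment(True) == pytest.approx(math.log(0.6 / 0.4))
        assert cfg.log_upper == pytest.approx(math.log(0.9999 / 0.0001))
        # unbroken True stream accepts H1 after exactly ceil(9.2102/0.4055) = 23
        state = run_stream([True] * 100, cfg)
        assert state.status == "accept_H1"
        assert state.votes_seen == 23

    def test_alternating_stream_caps_and_ties_go_negative(self):
        cfg = SequentialTestConfig()
        state = run_stream([True, False] * 100, cfg)
        assert state.status == "capped"
        assert state.votes_seen == cfg.n_max == 100
        assert state.positives * 2 == state.votes_seen  # a 50/50 tie

    def test_symmetric_boundaries_and_vote_swap_negates_llr(self, rng):
        cfg = SequentialTestConfig()
        assert cfg.log_upper == pytest.approx(-cfg.log_lower)  # alpha == beta
        votes = list(rng.random(40) < 0.5)
        a = run_stream(votes, cfg)
        b = run_stream([not v for v in votes], cfg)
        assert a.log_lr == pytest.approx(-b.log_lr)

    def test_update_after_terminal_rejected(self):
        cfg = SequentialTestConfig()
        state = run_stream([True] * 23, cfg)
        with pytest.raises(ValueError):
            sprt_update(state, True, cfg)

    def test_n_min_delays_decision(self):
        cfg = SequentialTestConfig(n_min=30)
        state = run_stream([True] * 100, cfg)
        assert state.status == "accept_H1"
        assert state.votes_seen == 30

    @pytest.mark.parametrize(
        "kwargs",
        [dict(theta=0.0), dict(delta=0.6), dict(alpha=0.7), dict(n_max=0), dict(n_min=5, n_max=3)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SequentialTestConfig(**kwargs)

    def test_vectorised_simulator_agrees_with_scalar_updates(self, rng):
        cfg = SequentialTestConfig(alpha=0.01, beta=0.01, n_max=40)
        for p in (0.3, 0.5, 0.7):
            seed = int(rng.integers(2**31))
            dec_vec, used_vec = simulate_vote_streams(p, cfg, 300, np.random.default_rng(seed))
            r2 = np.random.default_rng(seed)
            votes = r2.random((300, cfg.n_max)) < p
            for i in range(300):
                state = run_stream(votes[i], cfg)
                expected = (
                    state.status == "accept_H1"
                    if state.status != "capped"
                    else state.positives * 2 > state.votes_seen
                )
                assert dec_vec[i] == expected
                assert used_vec[i] == state.votes_seen

    def test_error_rate_bounded_outside_indifference_region(self, rng):
        # smoke-scale version of the guarantee check (full scale in acceptance)
        cfg = SequentialTestConfig()
        dec, _ = simulate_vote_streams(0.7, cfg, 20_000, rng)
        assert (~dec).mean() <= cfg.alpha
        dec, _ = simulate_vote_streams(0.3, cfg, 20_000, rng)
        assert dec.mean() <= cfg.beta

    def test_mean_votes_shrink_as_p_leaves_threshold(self, rng):
        cfg = SequentialTestConfig()
        means = [simulate_vote_streams(p, cfg, 4000, rng)[1].mean() for p in (0.55, 0.7, 0.85, 0.95)]
        assert all(b < a for a, b in zip(means, means[1:]))
        assert means[-1] < cfg.n_max / 2


class TestDrawBag:
    def test_size_and_determinism(self, small_dataset):
        bag1 = draw_bag(small_dataset, np.random.default_rng(5))
        bag2 = draw_bag(small_dataset, np.random.default_rng(5))
        assert len(bag1) == small_dataset.n_samples
        np.testing.assert_array_equal(bag1, bag2)

    def test_expected_distinct_fraction(self, small_dataset, rng):
        m = small_dataset.n_samples
        fracs = [len(set(draw_bag(small_dataset, rng))) / m for _ in range(400)]
        expected = 1 - (1 - 1 / m) ** m  # ≈ 0.63
        assert np.mean(fracs) == pytest.approx(expected, abs=0.02)

    def test_single_class_bags_redrawn(self, rng):
        data = make_dataset(n_genes=5, n_samples=60, n_pos=1)
        y = data.labels.to_numpy()
        for _ in range(50):
            bag = draw_bag(data, rng)
            assert y[bag].any() and not y[bag].all()

    def test_bag_enrichment_matches_binomial_theory(self, rng):
        # bags from a set with a known minority of flipped samples are more
        # often cleaner than the original than dirtier
        data = make_dataset(n_genes=5, n_samples=40, n_pos=20)
        flipped = set(range(4))  # 10% bad
        fewer = more = 0
        n = 4000
        for _ in range(n):
            bag = draw_bag(data, rng)
            nbad = sum(1 for i in bag if i in flipped)
            fewer += nbad < 4
            more += nbad > 4
        advantage = (fewer - more) / n
        theory = enrichment_advantage(NoiseModel(40, 4))
        assert advantage > 0
        assert advantage == pytest.approx(theory, abs=3 * np.sqrt(0.5 / n) * 2)


class TestPredictInstance:
    def test_cap_one_gives_single_classifier_score(self, separable_dataset):
        cfg = SequentialTestConfig(n_max=1)
        features = select_top_features(separable_dataset, "ttest", k=10)
        inst = separable_dataset.matrix.iloc[:, 0]
        res = predict_instance(
            separable_dataset, inst, "knn", features, cfg, np.random.default_rng(0)
        )
        assert res.n_used == 1
        assert res.stop_reason == "cap"

    def test_deterministic_under_fixed_seed(self, separable_dataset):
        cfg = SequentialTestConfig()
        features = select_top_features(separable_dataset, "ttest", k=10)
        inst = separable_dataset.matrix.iloc[:, 0]
        runs = [
            predict_instance(separable_dataset, inst, "svm", features, cfg, np.random.default_rng(3))
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    @pytest.mark.parametrize("classifier", ["svm", "knn", "tree"])
    def test_deep_positive_instance_fast_accepted(self, separable_dataset, classifier):
        # an instance far inside the positive class should be accepted in the
        # ~23-vote fast regime with a high ensemble score, across many seeds
        cfg = SequentialTestConfig()
        features = select_top_features(separable_dataset, "ttest", k=10)
        inst = separable_dataset.matrix.iloc[:, :5].mean(axis=1)  # positive centroid
        for seed in range(20):
            res = predict_instance(
                separable_dataset, inst, classifier, features, cfg, np.random.default_rng(seed)
            )
            assert res.decision
            assert res.score > 0.5
            assert res.n_used <= 40, f"seed {seed}: n_used {res.n_used}"

    def test_score_is_mean_of_member_scores(self, separable_dataset):
        # independently replay the seeded bag stream with the same base
        # classifier and check the reported score is the member mean
        from sklearn.neighbors import KNeighborsClassifier

        cfg = SequentialTestConfig(n_max=7)
        features = select_top_features(separable_dataset, "ttest", k=10)
        inst = separable_dataset.matrix.iloc[:, 2]
        res = predict_instance(
            separable_dataset, inst, "knn", features, cfg, np.random.default_rng(9)
        )
        rng = np.random.default_rng(9)
        X = separable_dataset.matrix.loc[list(features.selected)].to_numpy().T
        y = separable_dataset.labels.to_numpy()
        xi = inst.loc[list(features.selected)].to_numpy()[None, :]
        scores = []
        for _ in range(res.n_used):
            idx = rng.integers(0, len(y), size=len(y))
            while not (y[idx].any() and not y[idx].all()):
                idx = rng.integers(0, len(y), size=len(y))
            clf = KNeighborsClassifier(n_neighbors=5).fit(X[idx], y[idx])
            scores.append(clf.predict_proba(xi)[0, list(clf.classes_).index(True)])
        assert res.score == pytest.approx(np.mean(scores))


class TestPredictDataset:
    def test_result_independent_of_test_set_composition(self, separable_dataset):
        cfg = SequentialTestConfig()
        features = select_top_features(separable_dataset, "ttest", k=10)
        test = make_dataset(n_genes=60, n_samples=8, n_pos=4, seed=42).matrix
        full = predict_dataset(separable_dataset, test, "knn", features, cfg, master_seed=1)
        solo = predict_dataset(
            separable_dataset, test[[test.columns[3]]], "knn", features, cfg, master_seed=1
        )
        assert solo[0] == full[3]

    def test_empty_test_set(self, separable_dataset):
        features = select_top_features(separable_dataset, "ttest", k=10)
        out = predict_dataset(
            separable_dataset, separable_dataset.matrix.iloc[:, :0], "knn",
            features, SequentialTestConfig(), master_seed=0,
        )
        assert out == []

    def test_n_used_never_exceeds_cap(self, separable_dataset):
        cfg = SequentialTestConfig(n_max=25)
        features = select_top_features(separable_dataset, "ttest", k=10)
        test = make_dataset(n_genes=60, n_samples=10, n_pos=5, seed=8).matrix
        res = predict_dataset(separable_dataset, test, "tree", features, cfg, master_seed=2)
        assert all(r.n_used <= 25 for r in res)


class TestFixedBagging:
    def test_single_full_train_bag_equals_no_bagging_baseline(self, separable_dataset):
        from scipy.special import expit
        from sklearn.svm import SVC

        features = select_top_features(separable_dataset, "ttest", k=10)
        test = separable_dataset.matrix.iloc[:, :4]
        res = fixed_bagging(
            separable_dataset, test, "svm", features, 1, master_seed=0, bootstrap=False
        )
        X = separable_dataset.matrix.loc[list(features.selected)].to_numpy().T
        clf = SVC(kernel="linear").fit(X, separable_dataset.labels.to_numpy())
        ref = expit(clf.decision_function(test.loc[list(features.selected)].to_numpy().T))
        np.testing.assert_allclose([r.score for r in res], ref)

    def test_reproducible_and_agrees_with_dynamic_on_easy_data(self, separable_dataset):
        features = select_top_features(separable_dataset, "ttest", k=10)
        test = separable_dataset.matrix.iloc[:, :6]
        a = fixed_bagging(separable_dataset, test, "knn", features, 30, master_seed=5)
        b = fixed_bagging(separable_dataset, test, "knn", features, 30, master_seed=5)
        assert a == b
        dyn = predict_dataset(
            separable_dataset, test, "knn", features, SequentialTestConfig(), master_seed=5
        )
        agree = np.mean([x.decision == y.decision for x, y in zip(a, dyn)])
        assert agree >= 5 / 6  # same data, same votes in distribution
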