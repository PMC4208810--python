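import math

import numpy as np
import pandas as pd
import pytest

from icpipe import (
    class_centroids,
    classify_sample,
    estimate_s0,
    sam_analyze,
    sam_qvalues,
    sam_statistic,
    select_signature,
)
from icpipe.types import DegenerateInputError


def two_class_matrix(rng, n_features=200, n_per=10, planted=0, shift=2.0):
    X = rng.normal(0, 1, (n_features, 2 * n_per))
    X[:planted, :n_per] += shift
    labels = np.array([1] * n_per + [2] * n_per)
    return X, labels


class TestSamStatistic:
    def test_hand_computed_d(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        labels = [1, 1, 1, 2, 2, 2]
        d, s = sam_statistic(X, labels, s0=0.0)
        # s = sqrt((1/3+1/3) * (2+2) / 4) = sqrt(2/3); d = -3 / s
        assert s[0] == pytest.approx(math.sqrt(2 / 3))
        assert d[0] == pytest.approx(-3 / math.sqrt(2 / 3))

    def test_equal_means_give_zero(self):
        X = np.array([[1.0, 2.0, 1.0, 2.0]])
        d, _ = sam_statistic(X, [1, 1, 2, 2], s0=0.0)
        assert d[0] == pytest.approx(0.0)

    def test_large_s0_shrinks_d_to_zero(self):
        rng = np.random.default_rng(0)
        X, labels = two_class_matrix(rng, 50, 5, planted=10)
        d_small, _ = sam_statistic(X, labels, s0=0.0)
        d_huge, _ = sam_statistic(X, labels, s0=1e9)
        assert np.abs(d_huge).max() < 1e-6 < np.abs(d_small).max()

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        X, labels = two_class_matrix(rng, 30, 5)
        d1, _ = sam_statistic(X, labels, s0=0.1)
        d2, _ = sam_statistic(X, 3 - labels, s0=0.1)  # swaps 1 <-> 2
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_small_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            sam_statistic(np.ones((3, 3)), [1, 2, 2], s0=0.0)


class TestEstimateS0:
    def test_identical_scatter_returns_zero(self):
        X = np.array([[0.0, 1.0, 0.0, 1.0], [2.0, 3.0, 2.0, 3.0]])
        assert estimate_s0(X, [1, 1, 2, 2]) == 0.0

    def test_wide_scatter_range_yields_positive_s0_and_stabilises(self):
        # small groups make the scatter estimate noisy, so |d| inflates in
        # the low-s windows unless a positive fudge factor damps it
        rng = np.random.default_rng(2)
        scales = 10 ** rng.uniform(np.log10(0.5), np.log10(5.0), 300)
        X = rng.normal(0, 1, (300, 6)) * scales[:, None]
        labels = np.array([1] * 3 + [2] * 3)
        s0 = estimate_s0(X, labels)
        assert s0 > 0

        def window_cv(s0_val):
            d, s = sam_statistic(X, labels, s0_val)
            order = np.argsort(s)
            meds = [np.median(np.abs(d[w])) for w in np.array_split(order, 10)]
            return np.std(meds, ddof=1) / np.mean(meds)

        assert window_cv(s0) < window_cv(0.0)

    def test_single_candidate_percentile(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (50, 8))
        labels = [1] * 4 + [2] * 4
        _, s = sam_statistic(X, labels, 0.0)
        s0 = estimate_s0(X, labels, percentiles=[50])
        assert s0 == pytest.approx(np.percentile(s, 50))


class TestSamQvalues:
    def test_exhaustive_enumeration_seed_independent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 4))
        labels = [1, 1, 2, 2]  # C(4,2)=6 distinct assignments
        q1 = sam_qvalues(X, labels, s0=0.1, n_permutations=100, seed=1)
        q2 = sam_qvalues(X, labels, s0=0.1, n_permutations=100, seed=99)
        np.testing.assert_array_equal(q1, q2)

    def test_q_in_unit_interval_and_monotone_in_abs_d(self):
        rng = np.random.default_rng(5)
        X, labels = two_class_matrix(rng, 100, 6, planted=10)
        d, _ = sam_statistic(X, labels, s0=0.2)
        q = sam_qvalues(X, labels, s0=0.2, n_permutations=200, seed=0)
        assert (q >= 0).all() and (q <= 1).all()
        order = np.argsort(-np.abs(d))
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_invariant_under_label_swap(self):
        rng = np.random.default_rng(6)
        X, labels = two_class_matrix(rng, 40, 5, planted=5)
        q1 = sam_qvalues(X, labels, s0=0.1, n_permutations=252, seed=3)
        q2 = sam_qvalues(X, 3 - labels, s0=0.1, n_permutations=252, seed=3)
        np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_null_data_rarely_called(self):
        calls = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X, labels = two_class_matrix(rng)
            res = sam_analyze(X, labels, n_permutations=500, seed=seed)
            calls.append(int((res.table["q"] < 0.05).sum()))
        assert np.median(calls) == 0

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(42)
        X, labels = two_class_matrix(rng, 220, 10, planted=20)
        res = sam_analyze(X, labels, n_permutations=500, seed=0)
        called = set(res.table.index[res.table["q"] < 0.05])
        tp = len(called & set(range(20)))
        assert tp >= 18
        assert (len(called) - tp) / max(len(called), 1) <= 0.15


class TestSignatureAndClassifier:
    def test_all_q_one_empty_signature(self):
        rng = np.random.default_rng(7)
        X, labels = two_class_matrix(rng, 50, 5)
        res = sam_analyze(X, labels, n_permutations=100, seed=0)
        res.table["q"] = 1.0
        assert select_signature(res, 0.02).empty

    def test_threshold_one_selects_everything(self):
        rng = np.random.default_rng(8)
        X, labels = two_class_matrix(rng, 30, 4)
        res = sam_analyze(X, labels, n_permutations=100, seed=0)
        sig = select_signature(res, 1.1)
        assert len(sig) == 30

    def test_up_in_class_follows_sign(self):
        rng = np.random.default_rng(9)
        X, labels = two_class_matrix(rng, 60, 8, planted=10, shift=3.0)
        res = sam_analyze(X, labels, n_permutations=500, seed=0)
        sig = select_signature(res, 0.05)
        planted = sig.loc[sig.index < 10] if len(sig) else sig
        up_planted = sig.loc[sig["feature"].isin(range(10)), "up_in"]
        assert (up_planted == 1).all()  # shifted up in class 1

    def test_profile_equal_to_centroid(self):
        values = pd.DataFrame(
            {"s1": [1.0, 2, 3], "s2": [1.1, 2.1, 3.1], "s3": [3.0, 2, 1], "s4": [3.1, 2.1, 1.1]},
            index=["f1", "f2", "f3"],
        )
        labels = [1, 1, 2, 2]
        cents = class_centroids(values, labels, ["f1", "f2", "f3"])
        cls, scores = classify_sample(cents[1], cents)
        assert cls == 1
        assert scores[1] == pytest.approx(1.0)

    def test_negated_pattern_assigned_to_other_class(self):
        values = pd.DataFrame(
            {"s1": [1.0, 2, 3], "s2": [1.0, 2, 3], "s3": [3.0, 2, 1], "s4": [3.0, 2, 1]},
            index=["f1", "f2", "f3"],
        )
        cents = class_centroids(values, [1, 1, 2, 2], ["f1", "f2", "f3"])
        profile = pd.Series([-1.0, -2, -3], index=["f1", "f2", "f3"])
        cls, _ = classify_sample(profile, cents)
        assert cls == 2

    def test_low_coverage_rejected(self):
        cents = pd.DataFrame({1: [1.0, 2, 3, 4], 2: [4.0, 3, 2, 1]},
                             index=["f1", "f2", "f3", "f4"])
        profile = pd.Series([1.0], index=["f1"])
        with pytest.raises(DegenerateInputError, match="50%"):
            classify_sample(profile, cents)

    def test_held_out_samples_assigned_correctly(self):
        rng = np.random.default_rng(10)
        n_feat, n_per = 80, 12
        X = rng.normal(0, 1, (n_feat, 2 * n_per))
        X[:20, :n_per] += 2.0
        X[20:40, n_per:] += 2.0
        labels = np.array([1] * n_per + [2] * n_per)
        cols = [f"s{i}" for i in range(2 * n_per)]
        values = pd.DataFrame(X, index=[f"f{i}" for i in range(n_feat)], columns=cols)
        train = values.iloc[:, [*range(8), *range(n_per, n_per + 8)]]
        train_labels = np.array([1] * 8 + [2] * 8)
        res = sam_analyze(train, train_labels, n_permutations=500, seed=0)
        sig = select_signature(res, 0.05)
        cents = class_centroids(train, train_labels, sig["feature"].tolist())
        correct = 0
        test_cols = [*range(8, n_per), *range(n_per + 8, 2 * n_per)]
        for j in test_cols:
            cls, _ = classify_sample(values.iloc[:, j], cents)
            correct += cls == (1 if j < n_per else 2)
        assert correct / len(test_cols) >= 0.95
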