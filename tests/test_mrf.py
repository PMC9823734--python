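import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegemotion import mrf
from eegemotion.data_io import FeatureTable, SplitSpec, stratified_split
from eegemotion.synthetic import GeneratorConfig, generate_dataset


class TestNodeMarginScore:
    def test_uniform_node_scores_zero(self):
        assert mrf.node_margin_score([1/3, 1/3, 1/3]) == pytest.approx(0.0)

    def test_pure_node(self):
        assert mrf.node_margin_score([1.0, 0.0, 0.0]) == pytest.approx(2/3)

    def test_two_class_mix(self):
        assert mrf.node_margin_score([0.5, 0.5, 0.0]) == pytest.approx(1/6)

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            mrf.node_margin_score([0.5, 0.2, 0.2])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6))
    def test_equals_sum_of_squares_identity(self, raw):
        """Σ_k f_k (f_k − 1/C) ≡ Σ f² − 1/C for any frequency vector."""
        f = np.array(raw) / np.sum(raw)
        direct = sum(fk * (fk - 1 / len(f)) for fk in f)
        assert mrf.node_margin_score(f) == pytest.approx(direct, abs=1e-12)


class TestEmpiricalLoss:
    def test_perfect_prediction(self):
        assert mrf.empirical_loss(np.array([1.0, 0.0, 0.0]), 0) == 0.0

    def test_uniform_prediction(self):
        loss = mrf.empirical_loss(np.array([1/3, 1/3, 1/3]), 2)
        assert loss == pytest.approx(math.log(3))

    def test_floor_engaged(self):
        loss = mrf.empirical_loss(np.array([0.0, 1.0, 0.0]), 0)
        assert loss == pytest.approx(-math.log(1e-12))


def _brute_force_split(X, y, w, feats, n_classes, inv_c):
    """Exhaustive search over every (feature, midpoint) pair."""
    parent = mrf._weighted_counts(y, w, n_classes)
    parent_score = mrf._margin_of_counts(parent, inv_c)
    total_w = w.sum()
    best = None
    for feat in sorted(feats):
        for thr in sorted(set((a + b) / 2
                              for a, b in itertools.pairwise(sorted(set(X[:, feat]))))):
            mask = X[:, feat] <= thr
            if mask.all() or not mask.any():
                continue
            cl = mrf._weighted_counts(y[mask], w[mask], n_classes)
            cr = mrf._weighted_counts(y[~mask], w[~mask], n_classes)
            wl, wr = w[mask].sum(), w[~mask].sum()
            score = (wl * mrf._margin_of_counts(cl, inv_c)
                     + wr * mrf._margin_of_counts(cr, inv_c)) / total_w
            if score > parent_score + 1e-12 and (best is None or score > best[2] + 1e-12):
                best = (feat, thr, score)
    return best


class TestBestSplit:
    def test_two_cluster_1d(self):
        X = np.array([[1.0], [2.0], [9.0], [10.0]])
        y = np.array([0, 0, 1, 1])
        s = mrf.best_split(X, y, np.ones(4), np.array([0]), 2)
        assert (s.feature, s.threshold) == (0, 5.5)
        assert s.score == pytest.approx(0.5)   # both children pure, C=2

    def test_pure_node_no_split(self):
        X = np.arange(6.0).reshape(-1, 1)
        y = np.zeros(6, dtype=int)
        assert mrf.best_split(X, y, np.ones(6), np.array([0]), 2) is None

    def test_empty_candidates_error(self):
        with pytest.raises(mrf.SearchError):
            mrf.best_split(np.ones((2, 1)), np.array([0, 1]), np.ones(2),
                           np.array([], dtype=int), 2)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        X = np.round(rng.standard_normal((n, 2)), 1)
        y = rng.integers(0, 3, size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        got = mrf.best_split(X, y, w, np.array([0, 1]), 3)
        want = _brute_force_split(X, y, w, [0, 1], 3, 1/3)
        if want is None:
            assert got is None
        else:
            assert (got.feature, got.threshold) == (want[0], want[1])
            assert got.score == pytest.approx(want[2], abs=1e-10)


@pytest.fixture(scope="module")
def forest_data():
    t = generate_dataset(GeneratorConfig(n_per_class=60, p=16,
                                         separability=6.0, seed=1))
    return stratified_split(t, SplitSpec(seed=1))


class TestFitPredict:
    def test_separable_recovery(self, forest_data):
        train, test = forest_data
        forest = mrf.fit_forest(train, mrf.MRFConfig(n_trees=50, seed=1))
        labels, probs = mrf.predict(forest, test)
        assert (labels == test.labels).mean() >= 0.95
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_null_data_chance_band(self):
        t = generate_dataset(GeneratorConfig(n_per_class=100, p=16,
                                             separability=0.0, seed=2))
        train, test = stratified_split(t, SplitSpec(seed=2))
        forest = mrf.fit_forest(train, mrf.MRFConfig(n_trees=50, seed=2))
        labels, _ = mrf.predict(forest, test)
        assert 0.23 <= (labels == test.labels).mean() <= 0.43

    def test_single_class_rejected(self):
        t = FeatureTable(np.random.default_rng(0).standard_normal((10, 2)),
                         ["a", "b"], np.zeros(10, dtype=int))
        with pytest.raises(mrf.FitError):
            mrf.fit_forest(t)

    def test_seeded_determinism(self, forest_data):
        train, test = forest_data
        cfg = mrf.MRFConfig(n_trees=20, seed=9)
        a, _ = mrf.predict(mrf.fit_forest(train, cfg), test)
        b, _ = mrf.predict(mrf.fit_forest(train, cfg), test)
        np.testing.assert_array_equal(a, b)

    def test_instance_weights_positive_sum_n(self, forest_data):
        train, _ = forest_data
        forest = mrf.fit_forest(train, mrf.MRFConfig(n_trees=20, seed=3,
                                                     weighting_rounds=1))
        assert np.all(forest.instance_weights > 0)
        assert forest.instance_weights.sum() == pytest.approx(train.n, abs=1e-9)

    def test_stump_forest_follows_rule(self):
        """One depth-1 tree on cleanly split 1-D data reproduces the rule."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        t = FeatureTable(X, ["a"], np.array([0, 0, 1, 1]))
        forest = mrf.fit_forest(t, mrf.MRFConfig(n_trees=1, max_depth=1, seed=4))
        labels, _ = mrf.predict(forest, np.array([[2.0], [9.0]]))
        assert labels.tolist() == [0, 1]

    def test_majority_vote_averaging(self):
        """Averaging leaf distributions that vote (a, a, b) yields a."""
        probs = np.mean([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]], axis=0)
        assert np.argmax(probs) == 0


class TestWeightingRounds:
    def test_weighting_does_not_inflate_oob_loss(self):
        """Mean OOB loss after one reweighting round, averaged over 10 seeds."""
        deltas = []
        for s in range(10):
            d = generate_dataset(GeneratorConfig(n_per_class=60, p=16,
                                                 separability=2.0, seed=100 + s))
            train, _ = stratified_split(d, SplitSpec(seed=s))
            f0 = mrf.fit_forest(train, mrf.MRFConfig(n_trees=30, weighting_rounds=0, seed=s))
            f1 = mrf.fit_forest(train, mrf.MRFConfig(n_trees=30, weighting_rounds=1, seed=s))
            deltas.append(mrf.mean_oob_loss(f1, train) - mrf.mean_oob_loss(f0, train))
        assert np.mean(deltas) <= 0.05


class TestVarianceWithMoreTrees:
    def test_more_trees_never_increase_accuracy_variance(self):
        data = generate_dataset(GeneratorConfig(n_per_class=40, p=8,
                                                separability=2.0, seed=7))
        train, test = stratified_split(data, SplitSpec(seed=7))
        accs = {T: [] for T in (10, 200)}
        for T in accs:
            for s in range(20):
                forest = mrf.fit_forest(train, mrf.MRFConfig(
                    n_trees=T, weighting_rounds=0, seed=s))
                labels, _ = mrf.predict(forest, test)
                accs[T].append((labels == test.labels).mean())
        assert np.std(accs[200]) <= np.std(accs[10])


@pytest.fixture(scope="module")
def ssl_setup():
    d = generate_dataset(GeneratorConfig(n_per_class=50, p=16,
                                         separability=4.0, seed=5))
    return stratified_split(d, SplitSpec(seed=5))


class TestSSLRefine:

    def test_empty_unlabeled_reproduces_seeded_fit(self, ssl_setup):
        train, test = ssl_setup
        cfg = mrf.MRFConfig(n_trees=20, seed=6)
        forest = mrf.fit_forest(train, cfg)
        refined = mrf.ssl_refine(forest, train, np.empty((0, train.p)), [1.0, 0.5])
        a, _ = mrf.predict(forest, test)
        b, _ = mrf.predict(refined, test)
        np.testing.assert_array_equal(a, b)

    def test_low_temperature_is_hard_argmax(self, ssl_setup):
        train, _ = ssl_setup
        cfg = mrf.MRFConfig(n_trees=20, seed=6)
        forest = mrf.fit_forest(train, cfg)
        rng = np.random.default_rng(0)
        unl = train.values + 0.01 * rng.standard_normal(train.values.shape)
        probs = mrf.predict_proba(forest, unl)
        refined = mrf.ssl_refine(forest, train, unl, [1e-10])
        # pseudo-labels in the tau->0 limit equal argmax: refit on them is
        # the same as refit on hard labels
        hard = np.argmax(probs, axis=1)
        merged = FeatureTable(np.vstack([train.values, unl]),
                              list(train.feature_names),
                              np.concatenate([train.labels, hard]))
        expected = mrf.fit_forest(merged, cfg)
        a, _ = mrf.predict(refined, train)
        b, _ = mrf.predict(expected, train)
        np.testing.assert_array_equal(a, b)

    def test_nondecreasing_schedule_rejected(self, ssl_setup):
        train, _ = ssl_setup
        forest = mrf.fit_forest(train, mrf.MRFConfig(n_trees=5, seed=0))
        with pytest.raises(mrf.ConfigError):
            mrf.ssl_refine(forest, train, train.values, [0.5, 1.0])

    def test_ssl_no_harm(self):
        """10% labeled + 90% pseudo-labeled is not worse than labeled-only."""
        diffs = []
        for s in range(10):
            d = generate_dataset(GeneratorConfig(n_per_class=50, p=16,
                                                 separability=4.0, seed=200 + s))
            train, test = stratified_split(d, SplitSpec(seed=s))
            rng = np.random.default_rng(s)
            lab = np.sort(rng.choice(train.n, size=train.n // 10, replace=False))
            unl = np.setdiff1d(np.arange(train.n), lab)
            labeled = train.select(lab)
            cfg = mrf.MRFConfig(n_trees=20, seed=s)
            base = mrf.fit_forest(labeled, cfg)
            acc0 = (mrf.predict(base, test)[0] == test.labels).mean()
            refined = mrf.ssl_refine(base, labeled, train.values[unl],
                                     mrf.geometric_schedule())
            acc1 = (mrf.predict(refined, test)[0] == test.labels).mean()
            diffs.append(acc1 - acc0)
        assert np.mean(diffs) >= -0.02


class TestDeterminismUnderPermutation:
    def test_row_order_invariance_of_split(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 3, size=30)
        w = np.ones(30)
        s1 = mrf.best_split(X, y, w, np.array([0, 1, 2]), 3)
        perm = rng.permutation(30)
        s2 = mrf.best_split(X[perm], y[perm], w[perm], np.array([0, 1, 2]), 3)
        assert (s1.feature, s1.threshold) == (s2.feature, s2.threshold)
        assert s1.score == pytest.approx(s2.score, abs=1e-12)
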