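import numpy as np
import pytest

from evoppi import (
    ConfusionCounts,
    PairExample,
    PipelineConfig,
    TargetStatConfig,
    confusion,
    cross_validate,
    metrics,
    ordered_target_statistic,
    pair_features,
    predict_proba,
    rank_predictions,
    roc_auc,
    train_classifier,
)


def separable_data(rng, n=100, d=2, gap=4.0):
    X = rng.normal(size=(n, d))
    y = (rng.random(n) < 0.5).astype(int)
    X[y == 1] += gap
    return X, y


class TestPairFeatures:
    def test_concatenation(self):
        np.testing.assert_array_equal(
            pair_features(np.array([1.0, 2.0]), np.array([3.0, 4.0])),
            [1.0, 2.0, 3.0, 4.0],
        )

    def test_self_pair_halves_equal(self, rng):
        f = rng.random(8)
        v = pair_features(f, f)
        np.testing.assert_array_equal(v[:8], v[8:])

    def test_length_is_twice_d(self, rng):
        for _ in range(100):
            d = int(rng.integers(1, 64))
            assert pair_features(rng.random(d), rng.random(d)).shape == (2 * d,)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            pair_features(rng.random(3), rng.random(4))


def brute_force_ots(categories, labels, sigma, p, a):
    """Independent prefix-counting oracle for the ordered target statistic."""
    out = [None] * len(categories)
    for pos, i in enumerate(sigma):
        s = sum(labels[j] for j in sigma[:pos] if categories[j] == categories[i])
        k = sum(1 for j in sigma[:pos] if categories[j] == categories[i])
        out[i] = (s + a * p) / (k + a)
    return out


class TestOrderedTargetStatistic:
    def test_first_item_gets_pure_prior(self):
        out = ordered_target_statistic(
            ["x"], [1], TargetStatConfig(prior_p=0.5, prior_weight=1.0, permutation=(0,)))
        assert out[0] == 0.5

    def test_worked_example(self):
        out = ordered_target_statistic(
            ["c", "c", "d"], [1, 0, 1],
            TargetStatConfig(prior_p=0.5, prior_weight=1.0, permutation=(0, 1, 2)))
        np.testing.assert_allclose(out, [0.5, 0.75, 0.5])

    def test_run_of_positives_approaches_one(self):
        n = 50
        out = ordered_target_statistic(
            ["c"] * n, [1] * n,
            TargetStatConfig(prior_p=0.5, prior_weight=1.0, permutation=tuple(range(n))))
        expected = [(k + 0.5) / (k + 1) for k in range(n)]
        np.testing.assert_allclose(out, expected)
        assert all(b > a for a, b in zip(out, out[1:]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 15))
            cats = [int(c) for c in rng.integers(0, 4, n)]
            labels = [int(l) for l in rng.integers(0, 2, n)]
            sigma = [int(s) for s in rng.permutation(n)]
            p, a = float(rng.random()), float(rng.random() * 3 + 0.1)
            cfg = TargetStatConfig(prior_p=p, prior_weight=a, permutation=tuple(sigma))
            np.testing.assert_allclose(
                ordered_target_statistic(cats, labels, cfg),
                brute_force_ots(cats, labels, sigma, p, a))

    def test_invalid_permutation(self):
        with pytest.raises(ValueError):
            ordered_target_statistic(["a", "b"], [0, 1],
                                     TargetStatConfig(permutation=(0, 0)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ordered_target_statistic(["a"], [0, 1])


class TestClassifiers:
    def test_gbdt_fits_separable_data(self, rng):
        X, y = separable_data(rng)
        model = train_classifier(X, y, kind="gbdt", seed=0)
        preds = (predict_proba(model, X) >= 0.5).astype(int)
        assert (preds == y).all()

    @pytest.mark.parametrize("kind", ["gbdt", "dt"])
    def test_seeded_determinism(self, rng, kind):
        X, y = separable_data(rng, gap=1.0)
        p1 = predict_proba(train_classifier(X, y, kind=kind, seed=3), X)
        p2 = predict_proba(train_classifier(X, y, kind=kind, seed=3), X)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("kind", ["gbdt", "nb", "lda", "svm", "dt", "knn"])
    def test_probabilities_in_unit_interval(self, rng, kind):
        X, y = separable_data(rng, n=60, gap=1.0)
        p = predict_proba(train_classifier(X, y, kind=kind, seed=0), X)
        assert p.shape == (60,) and ((p >= 0) & (p <= 1)).all()

    def test_single_class_rejected(self, rng):
        X = rng.random((10, 2))
        with pytest.raises(ValueError):
            train_classifier(X, np.ones(10, dtype=int))

    def test_nan_features_rejected(self, rng):
        X = rng.random((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_classifier(X, np.arange(10) % 2)

    def test_unknown_kind_lists_choices(self, rng):
        X, y = separable_data(rng, n=20)
        with pytest.raises(ValueError, match="gbdt"):
            train_classifier(X, y, kind="boosty")

    def test_width_mismatch_at_predict(self, rng):
        X, y = separable_data(rng, n=40)
        model = train_classifier(X, y, seed=0)
        with pytest.raises(ValueError):
            predict_proba(model, rng.random((5, 3)))

    def test_hard_labels_match_manual_threshold(self, rng):
        X, y = separable_data(rng, gap=1.0)
        model = train_classifier(X, y, kind="knn", seed=0)
        p = predict_proba(model, X)
        manual = [1 if s >= 0.5 else 0 for s in p]
        np.testing.assert_array_equal((p >= 0.5).astype(int), manual)


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_all_wrong(self):
        c = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert c.TP == 0 and c.TN == 0 and c.FP == 2 and c.FN == 2

    def test_matches_loop_oracle(self, rng):
        labels = rng.integers(0, 2, 200)
        preds = rng.integers(0, 2, 200)
        c = confusion(labels, preds)
        tp = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 1)
        tn = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 0)
        fp = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 1)
        fn = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 0)
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        assert c.total == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_chance_case(self):
        m = metrics(ConfusionCounts(TP=25, TN=25, FP=25, FN=25))
        assert m == {"ACC": 0.5, "PE": 0.5, "SN": 0.5, "MCC": 0.0}

    def test_derived_case_with_phi_oracle(self):
        m = metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
        assert m["ACC"] == pytest.approx(0.9)
        assert m["PE"] == pytest.approx(50 / 60)
        assert m["SN"] == 1.0
        # MCC is the Pearson correlation of the binary label/prediction vectors
        labels = np.array([1] * 50 + [0] * 40 + [0] * 10 + [1] * 0)
        preds = np.array([1] * 50 + [0] * 40 + [1] * 10 + [0] * 0)
        assert m["MCC"] == pytest.approx(np.corrcoef(labels, preds)[0, 1], abs=1e-12)

    def test_perfect_case(self):
        m = metrics(ConfusionCounts(TP=7, TN=5, FP=0, FN=0))
        assert m["ACC"] == 1.0 and m["MCC"] == 1.0

    def test_undefined_precision_is_nan_not_error(self):
        m = metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=5))
        assert np.isnan(m["PE"]) and np.isnan(m["MCC"])
        assert m["ACC"] == pytest.approx(10 / 15)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))


def pair_counting_auc(labels, scores):
    """Exhaustive P(score+ > score-) + 0.5 P(=) oracle."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        out = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert out["auc"] == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])["auc"] == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # force some ties
            out = roc_auc(labels, scores)
            assert out["auc"] == pytest.approx(pair_counting_auc(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_roc_points_are_valid_curve(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        out = roc_auc(labels, rng.random(30))
        pts = np.asarray(out["points"])
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]
        assert (np.diff(pts[:, 0]) >= 0).all()


@pytest.fixture(scope="module")
def bench(small_benchmark):
    return small_benchmark


@pytest.fixture(scope="module")
def fast_config(fast_dae_config):
    return PipelineConfig(dae=fast_dae_config,
                          classifier_params={"n_estimators": 80})


class TestCrossValidate:
    def test_stratified_folds_and_report_shape(self, bench, fast_config):
        report = cross_validate(bench.pairs,
                                {p.protein_id: p for p in bench.pssms},
                                fast_config, k=5, seed=2)
        assert len(report.per_fold) == 5
        for fold in report.per_fold:
            assert set(fold) == {"ACC", "PE", "SN", "MCC", "AUC"}
            assert -1 <= fold["MCC"] <= 1
            assert all(0 <= fold[m] <= 1 for m in ("ACC", "PE", "SN", "AUC"))
        assert all(report.std[m] >= 0 for m in report.std)

    def test_same_seed_identical_reports(self, bench, fast_config):
        pssms = {p.protein_id: p for p in bench.pssms}
        r1 = cross_validate(bench.pairs, pssms, fast_config, k=3, seed=9)
        r2 = cross_validate(bench.pairs, pssms, fast_config, k=3, seed=9)
        assert r1.to_json() == r2.to_json()

    def test_k_below_two_rejected(self, bench, fast_config):
        with pytest.raises(ValueError):
            cross_validate(bench.pairs, {p.protein_id: p for p in bench.pssms},
                           fast_config, k=1, seed=0)

    def test_format_table_has_fold_rows(self, bench, fast_config):
        report = cross_validate(bench.pairs,
                                {p.protein_id: p for p in bench.pssms},
                                fast_config, k=3, seed=2)
        table = report.format_table()
        assert "Average" in table and "ACC" in table
        assert len(table.splitlines()) == 1 + 3 + 1


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X, y = separable_data(rng, n=80, d=8)
    return train_classifier(X, y, kind="knn", seed=0)


class TestRankPredictions:
    def _candidates(self, feats_list):
        return [PairExample(id_a=f"a{i}", id_b=f"b{i}", features=f, label=0)
                for i, f in enumerate(feats_list)]

    def test_sorted_descending(self, fitted, rng):
        cands = self._candidates(list(rng.normal(size=(10, 8))))
        ranked = rank_predictions(fitted, cands)
        scores = [s for _, _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_is_lexicographic(self, fitted):
        same = np.zeros(8)
        cands = [PairExample(id_a=a, id_b=b, features=same, label=0)
                 for a, b in [("z", "y"), ("a", "b"), ("a", "a")]]
        ranked = rank_predictions(fitted, cands)
        assert [(a, b) for a, b, _ in ranked] == [("a", "a"), ("a", "b"), ("z", "y")]

    def test_top_n(self, fitted, rng):
        cands = self._candidates(list(rng.normal(size=(10, 8))))
        assert len(rank_predictions(fitted, cands, top_n=3)) == 3

    def test_empty_rejected(self, fitted):
        with pytest.raises(ValueError):
            rank_predictions(fitted, [])
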