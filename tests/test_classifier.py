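"""Difference features, randomized-search training, ROC/PR evaluation,
threshold selection and prediction ranking."""

import numpy as np
import pytest

from kce.classifier import (
    ClassifierError,
    FeatureRow,
    SearchSpace,
    build_difference_features,
    evaluate,
    permutation_control_auroc,
    rank_predictions,
    score_pairs,
    select_threshold,
    train_classifier,
)
from kce.embedding import EmbeddingModel, Vocabulary


@pytest.fixture(scope="module")
def tiny_embedding():
    tokens = ["pka", "pkb", "pkc", "cax", "cay"]
    vecs = np.array(
        [[1.0, 0.0, 2.0], [0.0, 1.0, -1.0], [3.0, 3.0, 3.0],
         [1.0, 0.0, 2.0], [0.5, 0.5, 0.5]]
    )
    vocab = Vocabulary(index={t: i for i, t in enumerate(tokens)},
                       counts=np.full(5, 10))
    return EmbeddingModel(vocabulary=vocab, input_vectors=vecs)


PK_MAP = {"A": "pka", "B": "pkb", "C": "pkc"}
CA_MAP = {"X": "cax", "Y": "cay"}


def separable_rows(n_pos=15, n_neg=60, dim=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos):
        v = rng.normal(size=dim) * 0.1
        v[0] += 5.0
        rows.append(FeatureRow(f"P{i}", "C", v, 1))
    for i in range(n_neg):
        v = rng.normal(size=dim) * 0.1
        v[0] -= 5.0
        rows.append(FeatureRow(f"N{i}", "C", v, 0))
    return rows


class TestFeatures:
    def test_identical_vectors_give_zero_difference(self, tiny_embedding):
        (row,) = build_difference_features([("A", "X")], tiny_embedding, PK_MAP, CA_MAP)
        np.testing.assert_array_equal(row.v, np.zeros(3))

    def test_swapping_subtraction_order_negates(self, tiny_embedding):
        (row,) = build_difference_features([("B", "Y")], tiny_embedding, PK_MAP, CA_MAP)
        (rev,) = build_difference_features(
            [("Y", "B")], tiny_embedding, {"Y": "cay"}, {"B": "pkb"}
        )
        np.testing.assert_allclose(rev.v, -row.v)

    def test_three_pair_fixture_matches_hand_arithmetic(self, tiny_embedding):
        rows = build_difference_features(
            [("A", "Y"), ("B", "X"), ("C", "Y")], tiny_embedding, PK_MAP, CA_MAP
        )
        expected = {
            ("A", "Y"): [0.5, -0.5, 1.5],
            ("B", "X"): [-1.0, 1.0, -3.0],
            ("C", "Y"): [2.5, 2.5, 2.5],
        }
        assert [(r.pk, r.cancer) for r in rows] == sorted(expected)  # deterministic order
        for r in rows:
            np.testing.assert_allclose(r.v, expected[(r.pk, r.cancer)])

    def test_unresolvable_pairs_dropped_all_missing_is_error(self, tiny_embedding):
        rows = build_difference_features(
            [("A", "X"), ("ZZ", "X")], tiny_embedding, PK_MAP, CA_MAP
        )
        assert len(rows) == 1
        with pytest.raises(ClassifierError):
            build_difference_features([("ZZ", "QQ")], tiny_embedding, PK_MAP, CA_MAP)


class TestTraining:
    def test_separable_rows_reach_perfect_training_auroc(self):
        rows = separable_rows()
        model = train_classifier(rows, SearchSpace(n_estimators=(50,), iterations=2, cv_folds=3))
        scores = score_pairs(model, rows)
        report = evaluate(scores, [r.label for r in rows])
        assert report.auroc == 1.0

    def test_same_seed_same_configuration_and_predictions(self):
        rows = separable_rows(seed=3)
        space = SearchSpace(n_estimators=(50, 100), iterations=4, cv_folds=3, seed=5)
        m1 = train_classifier(rows, space)
        m2 = train_classifier(rows, space)
        assert m1.best_params_ == m2.best_params_
        np.testing.assert_array_equal(score_pairs(m1, rows), score_pairs(m2, rows))

    def test_randomized_search_on_small_grid_matches_exhaustive_scan(self):
        """With a 4-point space and iterations >= 4, the sampled search must
        find the same argmax as an exhaustive grid scan."""
        from sklearn.model_selection import GridSearchCV
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(int)
        rows = [FeatureRow(f"P{i}", "C", X[i], int(y[i])) for i in range(80)]
        space = SearchSpace(
            n_estimators=(20, 40), max_depth=(2, 4), max_features=("sqrt",),
            min_samples_split=(2,), min_samples_leaf=(1,), bootstrap=(True,),
            iterations=4, cv_folds=3, seed=0,
        )
        searched = train_classifier(rows, space)
        grid = GridSearchCV(
            RandomForestClassifier(random_state=0, n_jobs=1),
            param_grid=space.param_distributions, cv=3, scoring="roc_auc",
        )
        grid.fit(X, y)
        assert searched.best_params_ == grid.best_params_
        assert searched.best_score_ == pytest.approx(grid.best_score_)

    def test_single_class_input_is_an_error(self):
        rows = [FeatureRow("P", "C", np.zeros(3), 1)] * 5
        with pytest.raises(ClassifierError):
            train_classifier(rows)


class TestScoring:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        rows = separable_rows(seed=1)
        model = train_classifier(rows, SearchSpace(n_estimators=(50,), iterations=1, cv_folds=3))
        return model, rows

    def test_scores_in_unit_interval_and_ordered(self, fitted):
        model, rows = fitted
        s = score_pairs(model, rows)
        assert np.all((0 <= s) & (s <= 1))
        pos = s[[i for i, r in enumerate(rows) if r.label == 1]]
        neg = s[[i for i, r in enumerate(rows) if r.label == 0]]
        assert pos.min() > neg.max()

    def test_batch_equals_row_by_row(self, fitted):
        model, rows = fitted
        batch = score_pairs(model, rows)
        single = np.concatenate([score_pairs(model, [r]) for r in rows])
        np.testing.assert_array_equal(batch, single)

    def test_dim_mismatch_is_an_error(self, fitted):
        model, _ = fitted
        with pytest.raises(ClassifierError):
            score_pairs(model, [FeatureRow("P", "C", np.zeros(99), 0)])


def brute_auroc(scores, labels):
    """Concordant-pair fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_average_precision(scores, labels):
    """Step-weighted sum sum_k (R_k - R_{k-1}) * P_k over descending scores."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    tp = fp = 0
    ap, prev_recall = 0.0, 0.0
    scores_sorted = np.asarray(scores)[order]
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores_sorted[j] == scores_sorted[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestEvaluate:
    def test_perfect_and_uninformative_classifiers(self):
        labels = [1, 0, 1, 0, 0]
        assert evaluate(labels, labels).auroc == 1.0
        assert evaluate(labels, labels).average_precision == 1.0
        flat = evaluate([0.5] * 5, labels)
        assert flat.auroc == 0.5

    def test_auroc_and_ap_match_brute_force_on_random_instances(self):
        """50 random instances of n=200 against pairwise-concordance and
        step-sum oracles."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = 200
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            # quantized scores force ties to be handled correctly
            scores = np.round(rng.random(n), 2)
            report = evaluate(scores, labels)
            assert report.auroc == pytest.approx(brute_auroc(scores, labels), abs=1e-12)
            assert report.average_precision == pytest.approx(
                brute_average_precision(scores, labels), abs=1e-12
            )

    def test_roc_endpoints_and_trapezoid_area(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(50) < 0.4).astype(int)
        scores = rng.random(50)
        report = evaluate(scores, labels)
        fpr = [p[0] for p in report.roc]
        tpr = [p[1] for p in report.roc]
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert report.auroc == pytest.approx(np.trapezoid(tpr, fpr))

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        labels = (rng.random(80) < 0.5).astype(int)
        scores = rng.random(80)
        a = evaluate(scores, labels).auroc
        b = evaluate(np.exp(3 * scores), labels).auroc
        assert a == pytest.approx(b)

    def test_negated_scores_flip_auroc(self):
        rng = np.random.default_rng(11)
        labels = (rng.random(60) < 0.5).astype(int)
        scores = rng.random(60)
        assert evaluate(-scores, labels).auroc == pytest.approx(
            1.0 - evaluate(scores, labels).auroc
        )

    def test_single_class_labels_rejected(self):
        with pytest.raises(ClassifierError):
            evaluate([0.1, 0.9], [1, 1])


class TestThresholds:
    def test_separable_scores_return_smallest_perfect_threshold(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        # smallest threshold attaining gmean 1 under score >= t is 0.8
        assert select_threshold(scores, labels, "gmean") == pytest.approx(0.8)

    def test_single_positive_with_top_score_f1_threshold(self):
        scores = [0.95, 0.4, 0.3]
        labels = [1, 0, 0]
        assert select_threshold(scores, labels, "f1_opt") == pytest.approx(0.95)

    @pytest.mark.parametrize("criterion", ["gmean", "f1_opt"])
    def test_matches_exhaustive_scan(self, criterion):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = 60
            labels = (rng.random(n) < 0.3).astype(int)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)
            best_val, best_thr = -1.0, None
            for thr in sorted(set(scores)):
                pred = scores >= thr
                tp = int((pred & (labels == 1)).sum())
                fp = int((pred & (labels == 0)).sum())
                fn = int((~pred & (labels == 1)).sum())
                tn = int((~pred & (labels == 0)).sum())
                if criterion == "gmean":
                    tpr = tp / (tp + fn) if tp + fn else 0
                    fpr = fp / (fp + tn) if fp + tn else 0
                    val = (tpr * (1 - fpr)) ** 0.5
                else:
                    val = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0
                if val > best_val + 1e-12:
                    best_val, best_thr = val, thr
            assert select_threshold(scores, labels, criterion) == pytest.approx(best_thr)

    def test_unknown_criterion(self):
        with pytest.raises(ClassifierError):
            select_threshold([0.5], [1], "accuracy")


class TestRanking:
    @pytest.fixture(scope="class")
    @staticmethod
    def ranked_setup():
        rows = separable_rows(seed=2)
        model = train_classifier(rows, SearchSpace(n_estimators=(50,), iterations=1, cv_folds=3))
        return model, rows

    def test_sorted_descending_with_flag_count(self, ranked_setup):
        model, rows = ranked_setup
        ranked = rank_predictions(model, rows, threshold=0.5)
        scores = [r["score"] for r in ranked]
        assert scores == sorted(scores, reverse=True)
        assert sum(r["above_threshold"] for r in ranked) == sum(s >= 0.5 for s in scores)
        assert [r["rank"] for r in ranked] == list(range(1, len(rows) + 1))

    def test_threshold_above_max_flags_nothing(self, ranked_setup):
        model, rows = ranked_setup
        ranked = rank_predictions(model, rows, threshold=2.0)
        assert sum(r["above_threshold"] for r in ranked) == 0

    def test_top_ten_matches_full_sort_oracle(self, ranked_setup):
        model, rows = ranked_setup
        ranked = rank_predictions(model, rows, threshold=0.5)
        scores = score_pairs(model, rows)
        oracle = sorted(
            range(len(rows)), key=lambda i: (-scores[i], rows[i].pk, rows[i].cancer)
        )[:10]
        assert [(r["pk"], r["cancer"]) for r in ranked[:10]] == [
            (rows[i].pk, rows[i].cancer) for i in oracle
        ]


def test_permutation_control_sits_near_half():
    rng = np.random.default_rng(31)
    labels = (rng.random(200) < 0.2).astype(int)
    scores = labels * 0.8 + rng.random(200) * 0.2  # strongly informative
    assert permutation_control_auroc(scores, labels, n_permutations=50, seed=0) == pytest.approx(
        0.5, abs=0.05
    )
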