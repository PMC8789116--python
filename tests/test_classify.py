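"""Classification backend, splitting, metrics and agreement statistics."""

import math

import numpy as np
import pytest

from tweetage.classify import (
    AGE,
    NO_AGE,
    ClassifierConfig,
    EvalCounts,
    LabeledTweet,
    extraction_eval_counts,
    featurize_ngrams,
    fleiss_kappa,
    predict,
    prf,
    stratified_split,
    train,
)
from tweetage.synthgen import as_labeled, generate_corpus, generate_rater_matrix

from conftest import make_tweet


def _labeled(n_age, n_no_age):
    out = []
    for i in range(n_age):
        out.append(LabeledTweet(make_tweet(f"I'm {20 + i % 60} years old", tweet_id=f"a{i}"), AGE, 20 + i % 60))
    for i in range(n_no_age):
        out.append(LabeledTweet(make_tweet(f"scored {10 + i % 80} points", tweet_id=f"n{i}"), NO_AGE))
    return out


class TestStratifiedSplit:
    def test_80_20_of_11000(self):
        corpus = _labeled(3543, 7457)  # 32% / 68% class mix
        train_set, test_set = stratified_split(corpus, 0.8, seed=0)
        assert len(train_set) == 8800 and len(test_set) == 2200
        # class proportions preserved within rounding
        age_train = sum(1 for t in train_set if t.label == AGE)
        assert abs(age_train - 0.8 * 3543) <= 1

    def test_exact_stratification_small(self):
        corpus = _labeled(5, 5)
        train_set, test_set = stratified_split(corpus, 0.8, seed=1)
        assert sum(1 for t in train_set if t.label == AGE) == 4
        assert sum(1 for t in train_set if t.label == NO_AGE) == 4

    def test_partition_properties(self):
        corpus = _labeled(32, 68)
        train_set, test_set = stratified_split(corpus, 0.8, seed=2)
        ids = lambda items: {t.tweet.tweet_id for t in items}
        assert ids(train_set) | ids(test_set) == ids(corpus)
        assert ids(train_set) & ids(test_set) == set()

    def test_reproducible(self):
        corpus = _labeled(20, 40)
        a = stratified_split(corpus, 0.8, seed=7)
        b = stratified_split(corpus, 0.8, seed=7)
        assert [t.tweet.tweet_id for t in a[0]] == [t.tweet.tweet_id for t in b[0]]

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_labeled(1, 9), 0.8, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_labeled(5, 5), 1.2, seed=0)


class TestFeaturize:
    def test_vocabulary_enumeration(self):
        _, vocab, _ = featurize_ngrams(["a b"], (1, 2))
        assert set(vocab) == {"a", "b", "a b"}

    def test_counts(self):
        matrix, vocab, _ = featurize_ngrams(["a a"], (1, 1))
        assert matrix[0, vocab.index("a")] == 2

    def test_ngram_token_count(self):
        # 3 tokens with n=1..3 yield 3 + 2 + 1 = 6 n-gram tokens
        matrix, _, _ = featurize_ngrams(["x y z"], (1, 3))
        assert matrix.sum() == 6

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            featurize_ngrams([""], (1, 1))


class TestSvmBackend:
    def test_separable_toy_corpus_fits_exactly(self):
        corpus = _labeled(10, 10)
        model = train(ClassifierConfig(seed=0), corpus)
        assert predict(model, corpus) == [t.label for t in corpus]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train(ClassifierConfig(), _labeled(5, 0))

    def test_conflicting_duplicate_labels_tolerated(self):
        corpus = _labeled(5, 5)
        clash = LabeledTweet(corpus[0].tweet, NO_AGE)
        train(ClassifierConfig(), corpus + [clash])  # no error

    def test_predict_empty(self):
        model = train(ClassifierConfig(), _labeled(5, 5))
        assert predict(model, []) == []

    def test_labels_from_two_class_set(self):
        model = train(ClassifierConfig(), _labeled(5, 5))
        labels = predict(model, ["whatever text", "21", ""])
        assert set(labels) <= {AGE, NO_AGE}

    def test_heldout_f1_on_synthetic_corpus(self):
        corpus = [as_labeled(s) for s in generate_corpus(2000, age_fraction=0.32, seed=11)]
        train_set, test_set = stratified_split(corpus, 0.8, seed=11)
        model = train(ClassifierConfig(seed=11), train_set)
        labels = predict(model, test_set)
        tp = sum(1 for t, p in zip(test_set, labels) if t.label == AGE and p == AGE)
        fp = sum(1 for t, p in zip(test_set, labels) if t.label == NO_AGE and p == AGE)
        fn = sum(1 for t, p in zip(test_set, labels) if t.label == AGE and p == NO_AGE)
        metrics = prf(EvalCounts(tp, fp, fn))
        assert metrics.f1 >= 0.95

    def test_neural_backend_requires_plugin(self):
        with pytest.raises(RuntimeError):
            train(ClassifierConfig(backend="neural"), _labeled(5, 5))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(cost_c=-1)
        with pytest.raises(ValueError):
            ClassifierConfig(ngram_range=(3, 1))


class TestPrf:
    def test_extraction_confusion_counts(self):
        # TP = 581, FP = 73 + 68, FN = 1 + 54 from a classifier-wired
        # extraction evaluation
        m = prf(EvalCounts(tp=581, fp=141, fn=55))
        r = m.rounded()
        assert r["precision"] == 0.805
        assert r["recall"] == 0.914
        assert math.isclose(m.f1, 2 * 581 / (2 * 581 + 141 + 55))

    def test_perfect(self):
        r = prf(EvalCounts(10, 0, 0)).rounded()
        assert r == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_zero_tp_reports_zero_f1_with_warning(self):
        with pytest.warns(UserWarning):
            m = prf(EvalCounts(0, 5, 5))
        assert m.precision == 0 and m.recall == 0 and m.f1 == 0
        assert m.warnings

    def test_undefined_marker_not_zero(self):
        m = prf(EvalCounts(0, 0, 5))
        assert m.precision is None
        assert m.rounded()["precision"] == "undefined"

    def test_scale_invariance(self):
        base = prf(EvalCounts(581, 141, 55))
        for k in (2, 10, 100):
            scaled = prf(EvalCounts(581 * k, 141 * k, 55 * k))
            assert math.isclose(scaled.precision, base.precision)
            assert math.isclose(scaled.recall, base.recall)
            assert math.isclose(scaled.f1, base.f1)

    def test_f1_between_precision_and_recall(self):
        m = prf(EvalCounts(581, 141, 55))
        assert min(m.precision, m.recall) <= m.f1 <= max(m.precision, m.recall)

    def test_subcount_consistency_enforced(self):
        with pytest.raises(ValueError):
            EvalCounts(tp=1, fp=5, fn=0, fp_wrong_age=1, fp_misclassified=1)


class TestExtractionEvalCounts:
    def test_categories(self):
        gold = [
            LabeledTweet(make_tweet("a", tweet_id="1"), AGE, 21),
            LabeledTweet(make_tweet("b", tweet_id="2"), AGE, 30),
            LabeledTweet(make_tweet("c", tweet_id="3"), AGE, 40),
            LabeledTweet(make_tweet("d", tweet_id="4"), AGE, 50),
            LabeledTweet(make_tweet("e", tweet_id="5"), NO_AGE),
            LabeledTweet(make_tweet("f", tweet_id="6"), NO_AGE),
        ]
        labels = [AGE, AGE, AGE, NO_AGE, AGE, NO_AGE]
        ages = [21, 29, None, None, 33, None]
        c = extraction_eval_counts(gold, labels, ages)
        assert (c.tp, c.fp, c.fn) == (1, 2, 2)
        assert c.fp_wrong_age == 1 and c.fp_misclassified == 1
        assert c.fn_no_extraction == 1 and c.fn_misclassified == 1


class TestFleissKappa:
    def test_perfect_agreement(self):
        ratings = [[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]]
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_random_raters_near_zero(self):
        matrix, _ = generate_rater_matrix(10000, 5, accuracy=0.5, seed=42)
        assert abs(fleiss_kappa(matrix)) < 0.05

    def test_hand_computed_matrix(self):
        # independent from-scratch evaluation of the kappa formula
        ratings = [[0, 0, 1], [0, 1, 1], [1, 1, 1], [0, 0, 0]]
        table = np.array([[2, 1], [1, 2], [0, 3], [3, 0]])
        n = 3
        p_i = ((table ** 2).sum(axis=1) - n) / (n * (n - 1))
        p_bar = p_i.mean()
        p_j = table.sum(axis=0) / table.sum()
        p_e = (p_j ** 2).sum()
        expected = (p_bar - p_e) / (1 - p_e)
        assert fleiss_kappa(ratings) == pytest.approx(expected)

    def test_single_category_undefined(self):
        assert math.isnan(fleiss_kappa([[1, 1], [1, 1]]))

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            fleiss_kappa([[1, 0]])
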