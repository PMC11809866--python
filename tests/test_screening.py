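"""Screening classifiers: featurisation, SMOTE, training protocol."""

import math

import numpy as np
import pytest

from saferec import (Account, LabeledCorpus, LexiconSet, harmlessness_score,
                     lexicon_featurize, load_demo_lexicons,
                     select_contemplation_cohort, smote_oversample,
                     tfidf_featurize, train_screener)


def corpus_of(texts_labels, positive="pos"):
    docs = tuple((f"u{i}", t, lab) for i, (t, lab) in enumerate(texts_labels))
    return LabeledCorpus(docs, positive_class=positive)


class TestTfidf:
    def test_ngram_enumeration_of_short_document(self):
        corpus = corpus_of([("a b c", "pos"), ("d", "neg")])
        _, vec = tfidf_featurize(corpus)
        grams = set(vec.get_feature_names_out())
        assert {"a", "b", "c", "a b", "b c", "a b c"} <= grams

    def test_ubiquitous_term_gets_minimal_idf(self):
        corpus = corpus_of([("tok x", "pos"), ("tok y", "neg"), ("tok z", "pos")])
        _, vec = tfidf_featurize(corpus)
        idf = dict(zip(vec.get_feature_names_out(), vec.idf_))
        assert idf["tok"] == pytest.approx(math.log(1.0) + 1.0)

    def test_idf_convention_hand_computation(self):
        # 3 docs; "rare" appears twice in one doc only: tf=2, df=1
        corpus = corpus_of([("rare rare common", "pos"),
                            ("common filler", "neg"),
                            ("common other", "pos")])
        X, vec = tfidf_featurize(corpus)
        names = list(vec.get_feature_names_out())
        row = X[0].toarray().ravel()
        raw = {}
        for gram in ("rare", "common"):
            tf = 2 if gram == "rare" else 1
            df = 1 if gram == "rare" else 3
            raw[gram] = tf * (math.log(4 / (1 + df)) + 1)
        ratio = row[names.index("rare")] / row[names.index("common")]
        assert ratio == pytest.approx(raw["rare"] / raw["common"])

    def test_rows_unit_l2_norm_unless_empty(self):
        corpus = corpus_of([("some words here", "pos"), ("", "neg")])
        X, _ = tfidf_featurize(corpus)
        norms = np.sqrt(X.multiply(X).sum(axis=1)).A.ravel()
        assert norms[0] == pytest.approx(1.0)
        assert norms[1] == 0.0


class TestLexiconFeatures:
    LEX = LexiconSet.from_dict({
        "ed": {"ed_terms": ["calories", "thinspo"]},
        "affect": {"sad_terms": ["sad", "crying"]},
    })

    def test_hand_counted_occurrence_rate(self):
        text = "calories calories and eight more filler tokens right here now"  # 10 tokens
        corpus = corpus_of([(text, "pos"), ("x", "neg")])
        X = lexicon_featurize(corpus, self.LEX)
        assert X[0, 0] == pytest.approx(0.2)

    def test_empty_text_zero_row(self):
        corpus = corpus_of([("", "pos"), ("sad", "neg")])
        X = lexicon_featurize(corpus, self.LEX)
        assert not X[0].any()

    def test_demo_configuration_has_84_features(self):
        lex = load_demo_lexicons()
        assert lex.n_features == 84
        sizes = [len(lexs) for _, lexs in lex.groups]
        assert sizes == [24, 29, 12, 10, 9]
        corpus = corpus_of([("i feel sad about calories", "pos"), ("ok", "neg")])
        assert lexicon_featurize(corpus, lex).shape[1] == 84


class TestSmote:
    def test_balanced_input_unchanged(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        y = np.array([0, 0, 1, 1])
        Xr, yr = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xr, X)
        np.testing.assert_array_equal(yr, y)

    def test_deficit_count_arithmetic(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(5, 1, (20, 3))])
        y = np.array([1] * 5 + [0] * 20)
        Xr, yr = smote_oversample(X, y, seed=0)
        assert len(Xr) == 40
        assert (yr == 1).sum() == (yr == 0).sum() == 20

    def test_originals_untouched_and_synthetic_on_minority_segments(self):
        rng = np.random.default_rng(1)
        X_min = rng.normal(0, 1, (6, 2))
        X_maj = rng.normal(10, 1, (18, 2))
        X = np.vstack([X_min, X_maj])
        y = np.array([1] * 6 + [0] * 18)
        Xr, yr = smote_oversample(X, y, seed=2)
        np.testing.assert_array_equal(Xr[:24], X)
        synth = Xr[24:]
        # each synthetic point lies on a segment between two minority points
        for s in synth:
            on_segment = False
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    d = X_min[j] - X_min[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    lam = (s - X_min[i]) @ d / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                            X_min[i] + lam * d, s, atol=1e-8):
                        on_segment = True
            assert on_segment

    def test_singleton_minority_raises_with_advice(self):
        X = np.zeros((4, 2))
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="duplicat"):
            smote_oversample(X, y)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = np.array([1] * 10 + [0] * 20)
        a = smote_oversample(X, y, seed=9)
        b = smote_oversample(X, y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])


def separable_corpus(n_pos=30, n_neg=30, divergence=1.0, seed=0):
    """Two groups with vocabulary overlap controlled by divergence."""
    rng = np.random.default_rng(seed)
    docs = []
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        words = []
        for _ in range(40):
            if rng.random() < divergence:
                words.append(f"{'p' if pos else 'n'}word{rng.integers(20)}")
            else:
                words.append(f"shared{rng.integers(20)}")
        docs.append((" ".join(words), "pos" if pos else "neg"))
    return corpus_of(docs)


class TestTrainScreener:
    @pytest.mark.parametrize("featurizer", ["tfidf", "lexicon"])
    def test_separable_corpus_recovered(self, featurizer):
        corpus = separable_corpus(divergence=1.0, seed=0)
        lex = None
        if featurizer == "lexicon":
            lex = LexiconSet.from_dict({
                "g": {"pos_terms": [f"pword{i}" for i in range(20)],
                      "neg_terms": [f"nword{i}" for i in range(20)]}})
        _, metrics = train_screener(corpus, featurizer=featurizer,
                                    lexicons=lex, seed=0)
        assert metrics["f1"] >= 0.9

    def test_shuffled_labels_give_chance_accuracy(self):
        # balanced corpus: the permutation null is 0.5 accuracy
        rng = np.random.default_rng(4)
        accs = []
        for seed in range(6):
            corpus = separable_corpus(n_pos=30, n_neg=30, divergence=1.0,
                                      seed=seed)
            labels = [d[2] for d in corpus.documents]
            perm = rng.permutation(labels)
            shuffled = LabeledCorpus(
                tuple((o, t, p) for (o, t, _), p in zip(corpus.documents, perm)),
                positive_class="pos")
            _, m = train_screener(shuffled, seed=seed)
            accs.append(m["accuracy"])
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_same_seed_identical_metrics(self):
        corpus = separable_corpus(divergence=0.6, seed=1)
        _, m1 = train_screener(corpus, seed=11)
        _, m2 = train_screener(corpus, seed=11)
        assert m1 == m2

    def test_single_class_corpus_rejected(self):
        corpus = corpus_of([("a", "pos"), ("b", "pos")])
        with pytest.raises(ValueError, match="both classes"):
            train_screener(corpus)

    def test_imbalance_triggers_oversampling_path(self):
        corpus = separable_corpus(n_pos=8, n_neg=52, divergence=1.0, seed=2)
        _, m = train_screener(corpus, seed=0)
        assert m["f1"] >= 0.8


class TestHarmlessnessScore:
    def test_planted_vocabulary_scores_separate(self):
        corpus = separable_corpus(divergence=1.0, seed=3)
        model, _ = train_screener(corpus, seed=0)
        harmless = Account(id="h", texts=["pword1 pword2 pword3 pword4"])
        harmful = Account(id="x", texts=["nword1 nword2 nword3 nword4"])
        assert harmlessness_score(model, harmless) > 0.5
        assert harmlessness_score(model, harmful) < 0.5
        assert 0.0 <= harmlessness_score(model, Account(id="e")) <= 1.0

    def test_unfitted_model_raises(self):
        from saferec import ScreeningModel
        model = ScreeningModel(featurizer="tfidf", classifier_kind="logistic")
        with pytest.raises(RuntimeError, match="not fitted"):
            model.predict_proba(["text"])


class TestContemplationCohort:
    def _model(self):
        corpus = separable_corpus(divergence=1.0, seed=5)
        model, _ = train_screener(corpus, seed=0)
        return model

    def test_threshold_and_ordering(self):
        model = self._model()
        strong = Account(id="b_strong", texts=["pword1 pword2 pword3"] * 5)
        weak = Account(id="a_weak", texts=["nword1 nword2"] * 5)
        cohort = select_contemplation_cohort(model, [weak, strong], threshold=0.95)
        assert cohort in ([], ["b_strong"])
        cohort_any = select_contemplation_cohort(model, [weak, strong],
                                                 threshold=0.0)
        probs = model.predict_proba([" ".join(weak.texts),
                                     " ".join(strong.texts)])
        assert cohort_any == [a for _, a in
                              sorted(zip(-probs, ["a_weak", "b_strong"]))]

    def test_ties_broken_by_ascending_id(self):
        model = self._model()
        a = Account(id="aa", texts=["pword1"])
        b = Account(id="bb", texts=["pword1"])
        cohort = select_contemplation_cohort(model, [b, a], threshold=0.0)
        assert cohort == ["aa", "bb"]
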