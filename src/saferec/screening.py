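"""Text classifiers for screening accounts: contemplation-stage detection
and harmful-vs-harmless discrimination.

Two featurisations are supported: a TF-IDF bag of 1-3-grams over each
user's concatenated texts, and a lexicon model whose features are
occurrence rates of curated term lists (linguistic dimensions, affect,
personal concerns, suicide-risk vocabulary, eating-disorder vocabulary).
Class imbalance is handled with SMOTE oversampling applied to training
data only; evaluation is on a stratified held-out split the oversampler
never sees.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .interests import tokenize

__all__ = [
    "LabeledCorpus",
    "LexiconSet",
    "ScreeningModel",
    "load_demo_lexicons",
    "tfidf_featurize",
    "lexicon_featurize",
    "smote_oversample",
    "train_screener",
    "harmlessness_score",
    "select_contemplation_cohort",
]


@dataclass(frozen=True)
class LabeledCorpus:
    """Binary-labelled user-level documents.

    Each owner appears exactly once: a user is represented by the
    concatenation of their texts.
    """

    documents: tuple[tuple[str, str, str], ...]  # (owner_id, text, label)
    positive_class: str

    def __post_init__(self) -> None:
        owners = [d[0] for d in self.documents]
        if len(owners) != len(set(owners)):
            raise ValueError("each owner must appear exactly once in the corpus")
        labels = {d[2] for d in self.documents}
        if len(labels) > 2:
            raise ValueError(f"corpus must be binary, got labels {sorted(labels)}")
        if self.documents and self.positive_class not in labels:
            raise ValueError(
                f"positive class {self.positive_class!r} absent from corpus")

    @property
    def texts(self) -> list[str]:
        return [d[1] for d in self.documents]

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if d[2] == self.positive_class else 0
                         for d in self.documents])

    @classmethod
    def from_accounts(cls, accounts: Iterable, positive_class: str,
                      label_fn=None) -> "LabeledCorpus":
        """Build a corpus from account records, concatenating each
        account's posted texts.  ``label_fn`` maps an account to its class
        string (default: the account's stored label value)."""
        docs = []
        for acc in accounts:
            label = label_fn(acc) if label_fn else acc.label.value
            docs.append((acc.id, " ".join(acc.texts), label))
        return cls(tuple(docs), positive_class)


@dataclass(frozen=True)
class LexiconSet:
    """Ordered groups of named term lists; one feature per lexicon."""

    groups: tuple[tuple[str, tuple[tuple[str, tuple[str, ...]], ...]], ...]

    @property
    def lexicons(self) -> list[tuple[str, tuple[str, ...]]]:
        return [lex for _, lexs in self.groups for lex in lexs]

    @property
    def n_features(self) -> int:
        return len(self.lexicons)

    @classmethod
    def from_yaml(cls, path) -> "LexiconSet":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "LexiconSet":
        groups = tuple(
            (gname, tuple((lname, tuple(terms)) for lname, terms in lexs.items()))
            for gname, lexs in payload.items())
        return cls(groups)


def load_demo_lexicons() -> LexiconSet:
    """The shipped synthetic demo lexicon set (84 lexicons in groups of
    24/29/12/10/9)."""
    ref = importlib.resources.files("saferec.data") / "demo_lexicons.yaml"
    with importlib.resources.as_file(ref) as path:
        return LexiconSet.from_yaml(path)


def tfidf_featurize(corpus: LabeledCorpus,
                    ngram_range: tuple[int, int] = (1, 3)):
    """TF-IDF features over word 1-3-grams of the concatenated texts.

    tf is the raw in-document count; idf = ln((1+N)/(1+df)) + 1; rows are
    L2-normalised.  Returns (matrix, fitted vectorizer).
    """
    if not corpus.documents:
        raise ValueError("empty corpus")
    vec = TfidfVectorizer(ngram_range=ngram_range, norm="l2",
                          smooth_idf=True, sublinear_tf=False,
                          token_pattern=r"(?u)\b\w+\b")
    X = vec.fit_transform(corpus.texts)
    return X, vec


def lexicon_featurize(corpus: LabeledCorpus, lexicons: LexiconSet) -> np.ndarray:
    """Occurrence-rate features: hits of each lexicon per token of text.

    Multi-word lexicon terms match consecutive token runs.  Empty texts
    yield zero rows.  Column order follows the LexiconSet order.
    """
    lexs = lexicons.lexicons
    X = np.zeros((len(corpus.documents), len(lexs)), dtype=float)
    compiled = []
    for _, terms in lexs:
        compiled.append([tuple(tokenize(t)) for t in terms])
    for row, (_, text, _) in enumerate(corpus.documents):
        toks = tokenize(text)
        n_tok = len(toks)
        if n_tok == 0:
            continue
        for col, patterns in enumerate(compiled):
            hits = 0
            for pat in patterns:
                L = len(pat)
                if L == 0:
                    continue
                hits += sum(1 for i in range(n_tok - L + 1)
                            if tuple(toks[i:i + L]) == pat)
            X[row, col] = hits / n_tok
    return X


def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: balance the classes by interpolated synthetic minority points.

    Each synthetic sample is x + lambda * (x_nn - x) with lambda ~ U(0, 1)
    and x_nn one of the k nearest minority neighbours of a minority point
    x, so synthetic points lie on segments between minority points.
    Original samples are never modified.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    deficit = n_maj - n_min
    if deficit == 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError(
            "minority class has a single sample; SMOTE cannot interpolate "
            "(duplicate the sample instead)")
    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # column 0 is the point itself
    base = rng.integers(0, n_min, size=deficit)
    nbr_choice = rng.integers(1, k + 1, size=deficit)
    lam = rng.random(deficit)
    neighbors = X_min[idx[base, nbr_choice]]
    synthetic = X_min[base] + lam[:, None] * (neighbors - X_min[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


def _make_classifier(kind: str, seed: int):
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if kind == "svm":
        return SVC(probability=True, random_state=seed)
    raise ValueError(f"unknown classifier kind: {kind!r}")


@dataclass
class ScreeningModel:
    """A fitted screening classifier plus its featurisation recipe."""

    featurizer: Literal["tfidf", "lexicon"]
    classifier_kind: str
    threshold: float = 0.5
    _vectorizer: object | None = field(default=None, repr=False)
    _lexicons: LexiconSet | None = field(default=None, repr=False)
    _clf: object | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self._clf is not None

    def _features(self, texts: Sequence[str]) -> np.ndarray:
        if self.featurizer == "tfidf":
            return self._vectorizer.transform(texts)
        docs = tuple((str(i), t, "x") for i, t in enumerate(texts))
        corpus = LabeledCorpus(docs, positive_class="x")
        return lexicon_featurize(corpus, self._lexicons)

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        """Positive-class probability for each text."""
        if not self.is_fitted:
            raise RuntimeError("model is not fitted")
        X = self._features(texts)
        proba = self._clf.predict_proba(X)
        pos_col = list(self._clf.classes_).index(1)
        return proba[:, pos_col]

    def score_account(self, account) -> float:
        return float(self.predict_proba([" ".join(account.texts)])[0])


def train_screener(corpus: LabeledCorpus,
                   featurizer: Literal["tfidf", "lexicon"] = "tfidf",
                   classifier_kind: Literal["logistic", "random_forest", "svm"] = "logistic",
                   lexicons: LexiconSet | None = None,
                   cv_folds: int = 5,
                   test_size: float = 0.3,
                   seed: int = 0) -> tuple[ScreeningModel, dict]:
    """Fit a screening classifier and evaluate it on an untouched test set.

    The corpus is split 70/30 with stratification; SMOTE runs on the
    training portion only (and inside each cross-validation fold), so the
    reported metrics come from data the oversampler and the fit never saw.
    Returns the fitted model and a metrics dict with positive-class
    precision/recall/F1, overall accuracy, and mean cross-validated F1 on
    the training portion.
    """
    y = corpus.labels
    if len(np.unique(y)) < 2:
        raise ValueError("corpus must contain both classes")
    texts = corpus.texts
    idx = np.arange(len(texts))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed)

    model = ScreeningModel(featurizer=featurizer, classifier_kind=classifier_kind)
    if featurizer == "tfidf":
        vec = TfidfVectorizer(ngram_range=(1, 3), norm="l2", smooth_idf=True,
                              token_pattern=r"(?u)\b\w+\b")
        X_train = vec.fit_transform([texts[i] for i in train_idx]).toarray()
        X_test = vec.transform([texts[i] for i in test_idx]).toarray()
        model._vectorizer = vec
    elif featurizer == "lexicon":
        if lexicons is None:
            lexicons = load_demo_lexicons()
        X_all = lexicon_featurize(corpus, lexicons)
        X_train, X_test = X_all[train_idx], X_all[test_idx]
        model._lexicons = lexicons
    else:
        raise ValueError(f"unknown featurizer: {featurizer!r}")
    y_train, y_test = y[train_idx], y[test_idx]

    # cross-validated F1 on the training split, SMOTE inside each fold
    cv_scores = []
    n_folds = min(cv_folds, np.bincount(y_train).min())
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (tr, va) in enumerate(skf.split(X_train, y_train)):
            if len(np.unique(y_train[tr])) < 2:
                continue
            Xr, yr = _maybe_smote(X_train[tr], y_train[tr], seed + fold)
            clf = _make_classifier(classifier_kind, seed)
            clf.fit(Xr, yr)
            cv_scores.append(f1_score(y_train[va], clf.predict(X_train[va]),
                                      zero_division=0))

    X_fit, y_fit = _maybe_smote(X_train, y_train, seed)
    clf = _make_classifier(classifier_kind, seed)
    clf.fit(X_fit, y_fit)
    model._clf = clf

    y_pred = clf.predict(X_test)
    metrics = {
        "precision": float(precision_score(y_test, y_pred, zero_division=0)),
        "recall": float(recall_score(y_test, y_pred, zero_division=0)),
        "f1": float(f1_score(y_test, y_pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_test, y_pred)),
        "cv_f1_mean": float(np.mean(cv_scores)) if cv_scores else float("nan"),
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
    }
    return model, metrics


def _maybe_smote(X, y, seed):
    counts = np.bincount(y)
    if counts.min() >= 2 and counts[0] != counts[1]:
        return smote_oversample(X, y, seed=seed)
    return X, y


def harmlessness_score(model: ScreeningModel, account) -> float:
    """Probability that the account is harmless; higher = less harmful."""
    return model.score_account(account)


def select_contemplation_cohort(model: ScreeningModel, accounts: Iterable,
                                threshold: float = 0.95) -> list[str]:
    """Account ids whose contemplation probability exceeds ``threshold``,
    sorted by descending probability (ties broken by ascending id)."""
    scored = [(model.score_account(acc), acc.id) for acc in accounts]
    kept = [(p, aid) for p, aid in scored if p > threshold]
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [aid for _, aid in kept]
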