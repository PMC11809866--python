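"""Interest vectors, min-max normalisation, cosine content score, and
survey-profile expansion.

An account's topics of interest are estimated from three sources: the texts
it posts, the texts it likes, and the biographies of its followees.  Each
source is scanned for keywords of a fixed topic vocabulary; the resulting
bag-of-topics counts are min-max normalised (jointly across a cohort for
platform accounts, within-owner for survey participants) and compared with
cosine similarity.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TopicVocabulary",
    "load_demo_vocabulary",
    "InterestVector",
    "SurveyResponse",
    "tokenize",
    "extract_raw_interests",
    "minmax_normalize",
    "content_score",
    "expand_survey_profile",
    "rank_terms",
]

_TOKEN_RE = re.compile(r"[^\w\s]+", re.UNICODE)

#: Per-source cap on the number of texts scanned for keywords.
SOURCE_CAP = 200


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return _TOKEN_RE.sub(" ", text.lower()).split()


@dataclass(frozen=True)
class TopicVocabulary:
    """Ordered topic list plus a keyword -> topics map.

    The topic order is fixed at construction and defines the coordinate
    system of every :class:`InterestVector` built against this vocabulary.
    Keywords may be multi-word phrases; matching is done on the token
    stream after :func:`tokenize`.
    """

    topics: tuple[str, ...]
    keyword_map: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        known = set(self.topics)
        for kw, tset in self.keyword_map.items():
            unknown = set(tset) - known
            if unknown:
                raise ValueError(
                    f"keyword {kw!r} maps to unknown topics {sorted(unknown)}")

    @classmethod
    def from_dict(cls, topics: Sequence[str],
                  keyword_map: Mapping[str, Iterable[str]]) -> "TopicVocabulary":
        return cls(tuple(topics),
                   {tokenize_key(k): frozenset(v) for k, v in keyword_map.items()})

    def index(self, topic: str) -> int:
        return self.topics.index(topic)

    def __len__(self) -> int:
        return len(self.topics)

    def count_topics(self, texts: Iterable[str]) -> np.ndarray:
        """Keyword-occurrence counts per topic over a collection of texts."""
        counts = np.zeros(len(self.topics), dtype=float)
        idx = {t: i for i, t in enumerate(self.topics)}
        # split keywords by phrase length for n-gram matching
        by_len: dict[int, dict[tuple[str, ...], frozenset[str]]] = {}
        for kw, tset in self.keyword_map.items():
            parts = tuple(kw.split())
            by_len.setdefault(len(parts), {})[parts] = tset
        for text in texts:
            toks = tokenize(text)
            for n, table in by_len.items():
                if n == 0:
                    continue
                for i in range(len(toks) - n + 1):
                    gram = tuple(toks[i:i + n])
                    tset = table.get(gram)
                    if tset:
                        for t in tset:
                            counts[idx[t]] += 1
        return counts


def tokenize_key(keyword: str) -> str:
    """Canonical single-space, lowercase form of a keyword phrase."""
    return " ".join(tokenize(keyword))


def load_demo_vocabulary() -> tuple[TopicVocabulary, dict[str, list[str]]]:
    """The shipped demo topic vocabulary.

    Returns the vocabulary and the subcategory -> topics map used for
    survey-profile expansion.
    """
    import importlib.resources

    import yaml

    ref = importlib.resources.files("saferec.data") / "demo_vocabulary.yaml"
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    vocab = TopicVocabulary.from_dict(payload["topics"], payload["keywords"])
    return vocab, payload.get("subcategory_topics", {})


@dataclass
class InterestVector:
    """Bag-of-topics scores for one owner, raw and normalised."""

    owner_id: str
    raw: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if np.any(self.raw < 0):
            raise ValueError("raw interest scores must be non-negative")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)


@dataclass
class SurveyResponse:
    """One participant's survey answers.

    ``subcategory_scores`` holds 0-5 interest levels for the survey's
    subcategories; ``free_keywords`` holds the participant's own example
    keywords per subcategory (e.g. "PlayStation" under "videogames").
    """

    participant_id: str
    subcategory_scores: Mapping[str, int]
    free_keywords: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, score in self.subcategory_scores.items():
            if not 0 <= int(score) <= 5:
                raise ValueError(
                    f"score for {sub!r} must be an integer 0-5, got {score}")


def extract_raw_interests(account, vocab: TopicVocabulary,
                          source_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                          ) -> InterestVector:
    """Weighted bag-of-topics counts from posts, likes and followee bios.

    Each of the three sources is capped at :data:`SOURCE_CAP` texts; the
    per-source topic counts are combined with ``source_weights``
    (own posts, liked posts, followee biographies).
    """
    if len(vocab) == 0:
        raise ValueError("empty topic vocabulary")
    w_own, w_liked, w_bios = (float(w) for w in source_weights)
    if min(w_own, w_liked, w_bios) < 0:
        raise ValueError("source weights must be non-negative")
    raw = (w_own * vocab.count_topics(account.texts[:SOURCE_CAP])
           + w_liked * vocab.count_topics(account.liked_texts[:SOURCE_CAP])
           + w_bios * vocab.count_topics(account.followee_bios[:SOURCE_CAP]))
    return InterestVector(owner_id=account.id, raw=raw)


def minmax_normalize(cohort: Sequence[InterestVector],
                     mode: Literal["global", "per_owner"] = "global",
                     per_topic: bool = False) -> list[InterestVector]:
    """Fill ``normalized`` by min-max scaling of the raw scores.

    ``global`` scales with the min/max observed across the whole cohort —
    jointly over all (owner, topic) entries by default, per topic column
    when ``per_topic`` is set.  ``per_owner`` scales each owner by their
    own min/max (the survey-participant convention).  A degenerate range
    (max == min) maps to all zeros.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    mat = np.vstack([iv.raw for iv in cohort])
    if mode == "global":
        if per_topic:
            lo, hi = mat.min(axis=0), mat.max(axis=0)
        else:
            lo, hi = mat.min(), mat.max()
        span = np.where(hi - lo > 0, hi - lo, np.inf)
        for iv in cohort:
            iv.normalized = (iv.raw - lo) / span
    elif mode == "per_owner":
        for iv in cohort:
            lo, hi = iv.raw.min(), iv.raw.max()
            iv.normalized = (iv.raw - lo) / (hi - lo) if hi > lo else np.zeros_like(iv.raw)
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return list(cohort)


def content_score(v_u: InterestVector, v_cx: InterestVector) -> float:
    """Cosine similarity between two normalised interest vectors.

    Returns 0 when either vector is all-zero (no measurable interests).
    """
    a = v_u.normalized if v_u.normalized is not None else v_u.raw
    b = v_cx.normalized if v_cx.normalized is not None else v_cx.raw
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def expand_survey_profile(resp: SurveyResponse, vocab: TopicVocabulary,
                          concept_map: Mapping[str, Iterable[str]],
                          subcategory_topics: Mapping[str, Iterable[str]] | None = None,
                          ) -> InterestVector:
    """Turn survey answers into an interest vector over the topic vocabulary.

    Each subcategory's 0-5 score is propagated to the subcategory's own
    topics and, for every free keyword the participant supplied, to the
    keyword's topic and all its related concepts from ``concept_map`` (so a
    score of 4 on "videogames" with keyword "PlayStation" also scores
    "game console" 4).  Collisions keep the maximum propagated score, and
    the result is normalised within the participant.  Keywords that resolve
    to no known topic are logged and skipped.
    """
    raw = np.zeros(len(vocab), dtype=float)
    topic_idx = {t: i for i, t in enumerate(vocab.topics)}
    sub_topics = subcategory_topics or {}

    def bump(topic: str, score: float) -> bool:
        i = topic_idx.get(topic)
        if i is None:
            return False
        raw[i] = max(raw[i], score)
        return True

    for sub, score in resp.subcategory_scores.items():
        score = float(score)
        if score == 0:
            continue
        targets = set(sub_topics.get(sub, ()))
        if not targets:
            # the subcategory may itself be a topic or a mapped keyword
            targets = set(vocab.keyword_map.get(tokenize_key(sub), ()))
            if sub in topic_idx:
                targets.add(sub)
        for t in targets:
            bump(t, score)
        for kw in resp.free_keywords.get(sub, ()):
            related = set(concept_map.get(kw, ()))
            related |= set(vocab.keyword_map.get(tokenize_key(kw), ()))
            if kw in topic_idx:
                related.add(kw)
            hit = False
            for t in related | {kw}:
                hit = bump(t, score) or hit
            if not hit:
                logger.warning("unresolvable survey keyword %r (participant %s)",
                               kw, resp.participant_id)
    iv = InterestVector(owner_id=resp.participant_id, raw=raw)
    minmax_normalize([iv], mode="per_owner")
    return iv


def rank_terms(texts: Iterable[str], top_n: int = 10,
               ngrams: tuple[int, ...] = (1, 2)) -> list[tuple[str, int]]:
    """Most frequent unigrams and bigrams across a text collection.

    Ranked by descending frequency, ties broken lexicographically.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    counts: Counter[str] = Counter()
    for text in texts:
        toks = tokenize(text)
        for n in ngrams:
            for i in range(len(toks) - n + 1):
                counts[" ".join(toks[i:i + n])] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]
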