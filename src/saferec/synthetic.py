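"""Seeded generator of synthetic follow graphs, account texts and follow
decisions.

The generator emulates the structure the recommender assumes about its
(restricted) study population: labelled account groups — contemplation-
stage targets, harmful, neutral and pro-recovery accounts — with strong
intra-group follow homophily, group-specific vocabularies whose weight
delta controls how separable the groups are for text classifiers, per-
account topic-interest profiles, and probabilistic follow decisions that
favour high content similarity and (for this population) harmful accounts.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import Account, Label, SocialGraph
from .interests import TopicVocabulary
from .ranking import RankedRecommendation

__all__ = [
    "ScenarioConfig",
    "default_scenario",
    "generate_graph",
    "generate_corpus",
    "generate_follow_decisions",
    "scenario_vocabulary",
]

GROUPS = ("contemplation", "harmful", "neutral", "pro_recovery")

#: Graph label per generator group. Contemplation-stage accounts are
#: treated as harmful for screening purposes: the aim is never to
#: recommend peers likely to share pro-AN content.
GROUP_LABEL = {
    "contemplation": Label.HARMFUL,
    "harmful": Label.HARMFUL,
    "neutral": Label.NEUTRAL,
    "pro_recovery": Label.PRO_RECOVERY,
}


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic study scenario.

    ``follow_probs[src][dst]`` is the independent probability of a follow
    edge from a member of ``src`` to a member of ``dst``; ``delta`` in
    [0, 1] is the weight of the group-specific vocabulary when sampling
    text tokens (0 makes all groups textually identical); the betas drive
    the logistic follow-decision model.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "contemplation": 6, "harmful": 60, "neutral": 50, "pro_recovery": 15})
    follow_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "contemplation": {"contemplation": 0.10, "harmful": 0.30,
                          "neutral": 0.08, "pro_recovery": 0.02},
        "harmful": {"contemplation": 0.05, "harmful": 0.20,
                    "neutral": 0.03, "pro_recovery": 0.005},
        "neutral": {"contemplation": 0.005, "harmful": 0.03,
                    "neutral": 0.15, "pro_recovery": 0.04},
        "pro_recovery": {"contemplation": 0.005, "harmful": 0.01,
                         "neutral": 0.08, "pro_recovery": 0.20},
    })
    delta: float = 0.8
    topic_concentration: dict[str, float] = field(default_factory=lambda: {
        g: 1.0 for g in GROUPS})
    beta0: float = -1.0
    beta_content: float = 2.0
    beta_harm_affinity: float = 1.0
    n_topics: int = 10
    keywords_per_topic: int = 6
    group_vocab_size: int = 40
    docs_per_account: int = 20
    tokens_per_doc: int = 15
    likes_per_account: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g!r}")
        for src, row in self.follow_probs.items():
            for dst, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"follow probability {src}->{dst} = {p} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "ScenarioConfig":
        return cls(**json.loads(payload))


def default_scenario() -> ScenarioConfig:
    """The shipped study scenario.

    Sized and wired so that a contemplation target's *unfiltered*
    3-hop candidate pool is majority-harmful (the homophily trap a plain
    recommender falls into) while the harmlessness-filtered pool is
    majority-harmless, and so that at delta = 0.8 the group vocabularies
    support accurate harmlessness screening.
    """
    return ScenarioConfig()


def _account_ids(cfg: ScenarioConfig) -> list[tuple[str, str]]:
    """Deterministic (id, group) pairs; ids carry a group prefix."""
    pairs = []
    for g in GROUPS:
        for i in range(cfg.group_sizes.get(g, 0)):
            pairs.append((f"{g[:4]}_{i:03d}", g))
    return pairs


def scenario_vocabulary(cfg: ScenarioConfig) -> TopicVocabulary:
    """The topic vocabulary implied by a scenario.

    Topic ``topic_t`` owns keywords ``t<t>_kw<j>``; group vocabulary words
    are deliberately absent so interest extraction sees only the topic
    channel.
    """
    topics = [f"topic_{t}" for t in range(cfg.n_topics)]
    keyword_map = {
        f"t{t}_kw{j}": frozenset({f"topic_{t}"})
        for t in range(cfg.n_topics) for j in range(cfg.keywords_per_topic)}
    return TopicVocabulary(tuple(topics), keyword_map)


def generate_graph(cfg: ScenarioConfig) -> SocialGraph:
    """Draw the follow graph: independent Bernoulli edges with group-pair
    probabilities, no self-loops; contemplation accounts are targets."""
    rng = np.random.default_rng(cfg.seed)
    pairs = _account_ids(cfg)
    accounts = [Account(id=aid, label=GROUP_LABEL[g], is_target=(g == "contemplation"))
                for aid, g in pairs]
    graph = SocialGraph(accounts)
    for aid, g in pairs:
        row = cfg.follow_probs.get(g, {})
        for bid, h in pairs:
            if aid == bid:
                continue
            p = row.get(h, 0.0)
            if p > 0 and rng.random() < p:
                graph.add_edge(aid, bid)
    return graph


def account_group(account_id: str) -> str:
    """Recover the generator group from a synthetic account id."""
    prefix = account_id.split("_", 1)[0]
    for g in GROUPS:
        if g.startswith(prefix):
            return g
    raise ValueError(f"not a synthetic account id: {account_id!r}")


def generate_corpus(cfg: ScenarioConfig, graph: SocialGraph) -> SocialGraph:
    """Fill in texts, liked texts, bios and topic profiles for every account.

    Each token comes from the account's group vocabulary with probability
    ``delta`` and otherwise from the shared topic-keyword channel, where
    the topic is drawn from the account's own Dirichlet topic profile.
    With delta = 0 the groups are textually indistinguishable in
    distribution; with delta = 1 their vocabularies are disjoint.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_kw = cfg.keywords_per_topic

    def sample_doc(group: str, profile: np.ndarray, n_tokens: int) -> str:
        toks = []
        for _ in range(n_tokens):
            if rng.random() < cfg.delta:
                w = rng.integers(cfg.group_vocab_size)
                toks.append(f"{group}_w{w}")
            else:
                t = rng.choice(cfg.n_topics, p=profile)
                toks.append(f"t{t}_kw{rng.integers(n_kw)}")
        return " ".join(toks)

    for aid in sorted(graph.accounts):
        acc = graph.account(aid)
        group = account_group(aid)
        conc = cfg.topic_concentration.get(group, 1.0)
        profile = rng.dirichlet(np.full(cfg.n_topics, conc))
        acc.texts = [sample_doc(group, profile, cfg.tokens_per_doc)
                     for _ in range(cfg.docs_per_account)]
        acc.liked_texts = [sample_doc(group, profile, cfg.tokens_per_doc)
                           for _ in range(cfg.likes_per_account)]
        acc.bio = sample_doc(group, profile, cfg.tokens_per_doc)
    graph.attach_followee_bios()
    return graph


def generate_follow_decisions(cfg: ScenarioConfig,
                              recommendations: Sequence[RankedRecommendation],
                              labels: Mapping[str, Label],
                              seed: int | None = None) -> list[bool]:
    """Simulate whether each recommended account would be followed.

    Follow probability is logistic(beta0 + beta_content * content_score +
    beta_harm_affinity * [candidate is harmful]); draws are seeded
    Bernoulli.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    flags = []
    for rec in recommendations:
        harmful = labels[rec.candidate_id] == Label.HARMFUL
        logit = (cfg.beta0 + cfg.beta_content * rec.content_score
                 + cfg.beta_harm_affinity * (1.0 if harmful else 0.0))
        p = 1.0 / (1.0 + math.exp(-logit))
        flags.append(bool(rng.random() < p))
    return flags
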