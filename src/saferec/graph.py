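"""Directed follow-graph model and harmlessness-filtered candidate pools.

A follow graph is a directed graph whose nodes are platform accounts and
whose edge (u, v) means "u follows v"; v is a *followee* of u and u a
*follower* of v.  Candidate pools for contact recommendation are built by
expanding the followee neighbourhood of a target user, with a prior
filtering step that keeps only the followees a harmlessness classifier
scores above a threshold, so that the multi-hop expansion starts from
accounts unlikely to share harmful content.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Label",
    "Account",
    "SocialGraph",
    "CandidatePool",
    "followees",
    "followers",
    "filter_harmless",
    "build_candidate_pool",
]


class Label(str, Enum):
    """Ground-truth account type.

    ``harmless`` is deliberately absent: it is *defined* as the union of
    neutral and pro-recovery and always computed on demand.
    """

    HARMFUL = "harmful"
    NEUTRAL = "neutral"
    PRO_RECOVERY = "pro_recovery"
    UNKNOWN = "unknown"


@dataclass
class Account:
    """A platform account: identifier, texts, and an optional type label."""

    id: str
    label: Label = Label.UNKNOWN
    texts: list[str] = field(default_factory=list)
    liked_texts: list[str] = field(default_factory=list)
    bio: str = ""
    is_target: bool = False
    # Biographies of this account's followees, attached from the graph so
    # interest extraction can run on the record alone.
    followee_bios: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.label, Label):
            self.label = Label(self.label)

    @property
    def is_harmless(self) -> bool:
        """Harmless = neutral or pro-recovery (never stored as a label)."""
        return self.label in (Label.NEUTRAL, Label.PRO_RECOVERY)


class SocialGraph:
    """Directed follow graph over :class:`Account` records.

    Backed by a :class:`networkx.DiGraph`; edges run follower -> followee.
    Self-loops are rejected and every edge endpoint must be a known account.
    """

    def __init__(self, accounts: Iterable[Account] = (),
                 edges: Iterable[tuple[str, str]] = ()) -> None:
        self._g = nx.DiGraph()
        self.accounts: dict[str, Account] = {}
        for acc in accounts:
            self.add_account(acc)
        for u, v in edges:
            self.add_edge(u, v)

    def add_account(self, account: Account) -> None:
        if account.id in self.accounts:
            raise ValueError(f"duplicate account id: {account.id!r}")
        self.accounts[account.id] = account
        self._g.add_node(account.id)

    def add_edge(self, follower: str, followee: str) -> None:
        if follower == followee:
            raise ValueError(f"self-loop rejected: {follower!r}")
        for endpoint in (follower, followee):
            if endpoint not in self.accounts:
                raise KeyError(f"unknown account id: {endpoint!r}")
        self._g.add_edge(follower, followee)

    def __contains__(self, account_id: str) -> bool:
        return account_id in self.accounts

    def __len__(self) -> int:
        return len(self.accounts)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges())

    def account(self, account_id: str) -> Account:
        try:
            return self.accounts[account_id]
        except KeyError:
            raise KeyError(f"unknown account id: {account_id!r}") from None

    def followees(self, u: str) -> set[str]:
        if u not in self.accounts:
            raise KeyError(f"unknown account id: {u!r}")
        return set(self._g.successors(u))

    def followers(self, u: str) -> set[str]:
        if u not in self.accounts:
            raise KeyError(f"unknown account id: {u!r}")
        return set(self._g.predecessors(u))

    def attach_followee_bios(self, cap: int = 200) -> None:
        """Copy up to ``cap`` followee biographies onto each account record.

        Ids are sorted before truncation so the attached sample is
        deterministic.
        """
        for uid, acc in self.accounts.items():
            ids = sorted(self.followees(uid))[:cap]
            acc.followee_bios = [self.accounts[v].bio for v in ids]


def followees(graph: SocialGraph, u: str) -> set[str]:
    """Accounts that ``u`` follows (out-neighbours of ``u``)."""
    return graph.followees(u)


def followers(graph: SocialGraph, u: str) -> set[str]:
    """Accounts following ``u`` (in-neighbours of ``u``)."""
    return graph.followers(u)


def filter_harmless(graph: SocialGraph, ids: Iterable[str],
                    scorer: Callable[[Account], float],
                    threshold: float = 0.5) -> set[str]:
    """Keep the accounts whose harmlessness score reaches ``threshold``.

    ``scorer`` maps an :class:`Account` to a harmless-class probability in
    [0, 1]; anything outside that range is a contract violation.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept: set[str] = set()
    for uid in ids:
        score = float(scorer(graph.account(uid)))
        if not 0.0 <= score <= 1.0:
            raise ValueError(
                f"harmlessness scorer returned {score} for {uid!r}; "
                "scores must lie in [0, 1]")
        if score >= threshold:
            kept.add(uid)
    return kept


@dataclass(frozen=True)
class CandidatePool:
    """Multiset of recommendation candidates for one target user.

    ``counts`` holds, for each *sampled* candidate, the number of distinct
    penultimate-level accounts that follow it (its arrival multiplicity);
    ``total`` is the sum of those retained multiplicities and is the
    denominator of the occurrences ratio.
    """

    target_id: str
    counts: Mapping[str, int]
    sampled_ids: tuple[str, ...]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sampled_ids)

    def __contains__(self, candidate_id: str) -> bool:
        return candidate_id in self.counts


def build_candidate_pool(graph: SocialGraph, u: str,
                         scorer: Callable[[Account], float],
                         threshold: float = 0.5,
                         depth: int = 3,
                         pool_size: int = 100,
                         seed: int = 0) -> CandidatePool:
    """Expand ``u``'s filtered neighbourhood to ``depth`` hops and sample a pool.

    Level 1 is ``u``'s followees restricted by :func:`filter_harmless`;
    each further level is the union of followees of the previous one;
    candidates arrive as the multiset of followees of the penultimate
    level.  The target and all of its direct followees are never eligible.
    ``pool_size`` distinct candidates are drawn uniformly without
    replacement (seeded; candidate ids are sorted first so the draw is
    platform-independent), and each sampled candidate keeps its
    pre-sampling arrival multiplicity.
    """
    if depth < 2:
        raise ValueError(f"depth must be >= 2, got {depth}")
    if pool_size < 1:
        raise ValueError(f"pool_size must be >= 1, got {pool_size}")

    direct = graph.followees(u)
    level = filter_harmless(graph, direct, scorer, threshold)
    # walk to the penultimate level (depth-1 hops from u)
    for _ in range(depth - 2):
        level = set().union(*(graph.followees(w) for w in level)) if level else set()
        level.discard(u)

    ineligible = {u} | direct
    arrivals: Counter[str] = Counter()
    for w in sorted(level):
        for c in graph.followees(w):
            if c not in ineligible:
                arrivals[c] += 1

    eligible = sorted(arrivals)
    rng = np.random.default_rng(seed)
    if len(eligible) > pool_size:
        sampled = sorted(rng.choice(eligible, size=pool_size, replace=False))
    else:
        sampled = eligible
    counts = {c: arrivals[c] for c in sampled}
    return CandidatePool(target_id=u, counts=counts, sampled_ids=tuple(sampled))
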