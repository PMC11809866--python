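"""Candidate scoring and top-K assembly with a pro-recovery quota.

The rank score of a general candidate is

    rank = harmlessness * mean(content, topology)

where topology is the mean of the Jaccard similarity between followee sets
and the candidate's occurrences ratio in the pool, and content is the
cosine similarity of interest vectors.  Pro-recovery candidates are scored
without the topology term, and a fixed fraction of the final top-K slots
is reserved for the best-scoring pro-recovery accounts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .graph import CandidatePool, SocialGraph
from .interests import InterestVector, content_score

logger = logging.getLogger(__name__)

__all__ = [
    "RankedRecommendation",
    "occurrences_ratio",
    "jaccard_sim",
    "topology_score",
    "rank_score",
    "participants_rank_score",
    "score_candidate",
    "assemble_top_k",
]


@dataclass(frozen=True)
class RankedRecommendation:
    """One scored candidate with all score components."""

    candidate_id: str
    occurrences_ratio: float = 0.0
    jaccard: float = 0.0
    topology_score: float = 0.0
    content_score: float = 0.0
    harmlessness: float = 1.0
    rank_score: float = 0.0
    is_pro_recovery_slot: bool = False


def occurrences_ratio(pool: CandidatePool, cx: str) -> float:
    """Arrival multiplicity of ``cx`` over the pool's total multiplicity."""
    if pool.total <= 0:
        raise ValueError("empty candidate pool")
    return pool.counts.get(cx, 0) / pool.total


def jaccard_sim(graph: SocialGraph, u: str, cx: str) -> float:
    """Jaccard similarity of the followee sets of ``u`` and ``cx``.

    0 when both sets are empty.
    """
    a, b = graph.followees(u), graph.followees(cx)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def topology_score(graph: SocialGraph, u: str, cx: str,
                   pool: CandidatePool) -> float:
    """Mean of Jaccard similarity and occurrences ratio."""
    return (jaccard_sim(graph, u, cx) + occurrences_ratio(pool, cx)) / 2.0


def rank_score(harmlessness: float, content: float, topology: float,
               pro_recovery: bool = False,
               use_harmlessness: bool = True) -> float:
    """Harmlessness-weighted combination of content and topology.

    General candidates: harmlessness * mean(content, topology).
    Pro-recovery candidates: harmlessness * content (topology ignored);
    ``use_harmlessness=False`` drops the factor for the bare-content
    variant.
    """
    h = harmlessness if use_harmlessness else 1.0
    if pro_recovery:
        return h * content
    return h * (content + topology) / 2.0


def participants_rank_score(harmlessness: float, content: float) -> float:
    """Survey-participant variant: harmlessness * content (no topology)."""
    return harmlessness * content


def score_candidate(graph: SocialGraph, u: str, cx: str, pool: CandidatePool,
                    interests: Mapping[str, InterestVector],
                    harmlessness: float,
                    pro_recovery: bool = False) -> RankedRecommendation:
    """Compute every score component for one (target, candidate) pair."""
    occ = occurrences_ratio(pool, cx)
    jac = jaccard_sim(graph, u, cx)
    topo = (jac + occ) / 2.0
    cont = content_score(interests[u], interests[cx])
    rank = rank_score(harmlessness, cont, topo, pro_recovery=pro_recovery)
    return RankedRecommendation(
        candidate_id=cx, occurrences_ratio=occ, jaccard=jac,
        topology_score=topo, content_score=cont, harmlessness=harmlessness,
        rank_score=rank, is_pro_recovery_slot=pro_recovery)


def _round_half_up_int(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def assemble_top_k(ranked: Sequence[RankedRecommendation],
                   pro_recovery_pool: Sequence[RankedRecommendation],
                   K: int, quota: float = 0.2) -> list[RankedRecommendation]:
    """Merge general and pro-recovery candidates into a top-K list.

    ``quota`` of the K slots (round half-up) go to the highest-scoring
    pro-recovery candidates; the rest to the best general candidates.  The
    merged list is ordered by descending rank score with ties broken by
    ascending candidate id.  If the pro-recovery pool is too small the
    missing slots are backfilled with general candidates.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if not 0.0 <= quota <= 1.0:
        raise ValueError(f"quota must be in [0, 1], got {quota}")
    q = _round_half_up_int(quota * K)

    key = lambda r: (-r.rank_score, r.candidate_id)
    pr_sorted = sorted(pro_recovery_pool, key=key)
    pr_chosen = pr_sorted[:q]
    if len(pr_chosen) < q:
        logger.warning("pro-recovery pool has %d candidates for %d quota slots; "
                       "backfilling with general candidates", len(pr_chosen), q)
    taken = {r.candidate_id for r in pr_chosen}
    gen_sorted = [r for r in sorted(ranked, key=key) if r.candidate_id not in taken]
    general_chosen = gen_sorted[:K - len(pr_chosen)]

    merged = sorted(pr_chosen + general_chosen, key=key)
    return merged[:K]
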