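"""End-to-end orchestration: simulate -> screen -> recommend -> evaluate.

The pipeline generates (or loads) a follow graph, trains the harmlessness
screener on the labelled accounts, builds harmlessness-filtered candidate
pools for every target, ranks candidates under the proposed model and two
baselines, simulates follow decisions, and writes per-(model, K) metric
reports plus a reproducibility manifest.

Models compared
---------------
``proposed``       filtered pool + harmlessness factor + content & topology
                   + pro-recovery quota injection
``filtered_content`` filtered pool, ranked by content score alone
``no_filter``      unfiltered pool, content & topology, no harmlessness
                   factor, no quota (the plain contact-recommender baseline)
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import (AnnotatedRecommendationList, EvaluationReport,
                         aggregate_reports, compare_models, evaluate_list)
from .graph import Label, SocialGraph, build_candidate_pool
from .interests import extract_raw_interests, minmax_normalize
from .io import (write_annotation_csv, write_report_csv, write_report_json)
from .ranking import RankedRecommendation, assemble_top_k, score_candidate
from .screening import LabeledCorpus, ScreeningModel, train_screener
from .synthetic import (ScenarioConfig, default_scenario, generate_corpus,
                        generate_follow_decisions, generate_graph,
                        scenario_vocabulary)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "train_harmlessness_screener", "recommend_for_target"]

MODELS = ("proposed", "filtered_content", "no_filter")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenario: ScenarioConfig = field(default_factory=default_scenario)
    pool_size: int = 100
    depth: int = 3
    threshold: float = 0.5
    quota: float = 0.2
    k_grid: tuple[int, ...] = (5, 10, 15)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if list(self.k_grid) != sorted(self.k_grid):
            raise ValueError("k_grid must be ascending")


@dataclass
class PipelineResult:
    graph: SocialGraph
    screener_metrics: dict
    reports: list[EvaluationReport]
    annotations: dict[str, list[AnnotatedRecommendationList]]
    table: object  # pandas DataFrame from compare_models


def train_harmlessness_screener(graph: SocialGraph, seed: int = 0,
                                featurizer: str = "tfidf",
                                classifier_kind: str = "logistic",
                                ) -> tuple[ScreeningModel, dict]:
    """Fit harmful-vs-harmless on the labelled non-target accounts.

    Harmless (= neutral + pro-recovery) is the positive class; target
    accounts are excluded so screening generalisation is measured on
    accounts the recommender will actually filter.
    """
    accounts = [a for a in graph.accounts.values()
                if not a.is_target and a.label != Label.UNKNOWN]
    corpus = LabeledCorpus.from_accounts(
        accounts, positive_class="harmless",
        label_fn=lambda a: "harmless" if a.is_harmless else "harmful")
    return train_screener(corpus, featurizer=featurizer,
                          classifier_kind=classifier_kind, seed=seed)


def _build_interests(graph: SocialGraph, vocab):
    vectors = {uid: extract_raw_interests(graph.account(uid), vocab)
               for uid in sorted(graph.accounts)}
    minmax_normalize(list(vectors.values()), mode="global")
    return vectors


def recommend_for_target(graph: SocialGraph, target: str, model: str,
                         screener: ScreeningModel, interests, cfg: RunConfig,
                         ) -> list[RankedRecommendation]:
    """Produce a top-K_max recommendation list for one target under one model."""
    k_max = cfg.k_grid[-1]
    h_cache: dict[str, float] = {}

    def h(uid: str) -> float:
        if uid not in h_cache:
            h_cache[uid] = screener.score_account(graph.account(uid))
        return h_cache[uid]

    if model == "no_filter":
        scorer, threshold = (lambda a: 1.0), 0.0
    else:
        scorer, threshold = (lambda a: h(a.id)), cfg.threshold
    pool = build_candidate_pool(graph, target, scorer, threshold,
                                depth=cfg.depth, pool_size=cfg.pool_size,
                                seed=cfg.seed)
    if pool.total == 0:
        return []

    ranked = []
    for cx in pool.sampled_ids:
        harmlessness = 1.0 if model == "no_filter" else h(cx)
        rec = score_candidate(graph, target, cx, pool, interests,
                              harmlessness=harmlessness)
        if model == "filtered_content":
            rec = RankedRecommendation(
                candidate_id=rec.candidate_id,
                occurrences_ratio=rec.occurrences_ratio, jaccard=rec.jaccard,
                topology_score=rec.topology_score,
                content_score=rec.content_score, harmlessness=1.0,
                rank_score=rec.content_score)
        ranked.append(rec)

    if model == "proposed":
        direct = graph.followees(target)
        pr_pool = []
        for uid in sorted(graph.accounts):
            acc = graph.account(uid)
            if acc.label != Label.PRO_RECOVERY or uid == target or uid in direct:
                continue
            from .interests import content_score as _cs
            cont = _cs(interests[target], interests[uid])
            occ = pool.counts.get(uid, 0) / pool.total
            jac = 0.0
            pr_pool.append(RankedRecommendation(
                candidate_id=uid, occurrences_ratio=occ, jaccard=jac,
                topology_score=(jac + occ) / 2.0, content_score=cont,
                harmlessness=h(uid), rank_score=h(uid) * cont,
                is_pro_recovery_slot=True))
        return assemble_top_k(ranked, pr_pool, K=k_max, quota=cfg.quota)
    return assemble_top_k(ranked, [], K=k_max, quota=0.0)


def run_pipeline(cfg: RunConfig, graph: SocialGraph | None = None) -> PipelineResult:
    """Execute the full study pipeline; idempotent given the seeds."""
    t0 = time.time()
    if graph is None:
        scenario = cfg.scenario
        graph = generate_corpus(scenario, generate_graph(scenario))
    logger.info("graph: %d accounts, %d edges (%.1fs)",
                len(graph), len(graph.edges), time.time() - t0)

    screener, screener_metrics = train_harmlessness_screener(graph, seed=cfg.seed)
    logger.info("harmlessness screener: F1=%.3f acc=%.3f",
                screener_metrics["f1"], screener_metrics["accuracy"])

    vocab = scenario_vocabulary(cfg.scenario)
    interests = _build_interests(graph, vocab)
    labels = {uid: graph.account(uid).label for uid in graph.accounts}
    targets = sorted(uid for uid, acc in graph.accounts.items() if acc.is_target)

    annotations: dict[str, list[AnnotatedRecommendationList]] = {m: [] for m in MODELS}
    for model in MODELS:
        for i, target in enumerate(targets):
            recs = recommend_for_target(graph, target, model, screener,
                                        interests, cfg)
            if not recs:
                continue
            flags = generate_follow_decisions(
                cfg.scenario, recs, labels,
                seed=cfg.seed + 1000 + 17 * i + MODELS.index(model))
            annotations[model].append(AnnotatedRecommendationList(
                target_id=target,
                candidate_ids=tuple(r.candidate_id for r in recs),
                types=tuple(labels[r.candidate_id].value for r in recs),
                followed=tuple(flags)))

    reports: list[EvaluationReport] = []
    for model in MODELS:
        for k in cfg.k_grid:
            per_target = [evaluate_list(lst, min(k, lst.k_max), model=model)
                          for lst in annotations[model] if lst.k_max >= 1]
            if per_target:
                reports.append(aggregate_reports(per_target))
    table = compare_models(reports) if reports else None

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for model, lists in annotations.items():
            write_annotation_csv(out / f"annotations_{model}.csv", lists)
        if table is not None:
            write_report_csv(out / "report.csv", table)
        write_report_json(out / "report.json", reports)
        manifest = {
            "scenario": json.loads(cfg.scenario.to_json()),
            "pool_size": cfg.pool_size, "depth": cfg.depth,
            "threshold": cfg.threshold, "quota": cfg.quota,
            "k_grid": list(cfg.k_grid), "seed": cfg.seed,
            "screener_metrics": screener_metrics,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return PipelineResult(graph=graph, screener_metrics=screener_metrics,
                          reports=reports, annotations=annotations, table=table)
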