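"""Evaluation metrics for harm-aware recommendation lists.

Beyond precision / recall / average precision over "would follow"
annotations, the suite measures the composition of the suggestions: the
ratio of pro-recovery, neutral, harmful and harmless (= neutral +
pro-recovery) accounts suggested at K, followed over suggested of each
type, and followed over K — and the APHR score, the harmonic mean of
average precision and the harmless-followed ratio at K (HLFRK), which
strongly penalises models that only surface harmful accounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .graph import Label

__all__ = [
    "AnnotatedRecommendationList",
    "EvaluationReport",
    "precision_at_k",
    "recall_at_k",
    "average_precision",
    "type_ratios",
    "aphr",
    "evaluate_list",
    "aggregate_reports",
    "compare_models",
    "round_report",
]

_TYPES = ("harmful", "neutral", "pro_recovery")


@dataclass(frozen=True)
class AnnotatedRecommendationList:
    """A ranked recommendation list with per-candidate annotations.

    ``types`` holds the account-type label of each suggested candidate and
    ``followed`` whether the annotator / participant would follow it; both
    are aligned with ``candidate_ids`` and cover all K_max annotated
    positions.
    """

    target_id: str
    candidate_ids: tuple[str, ...]
    types: tuple[str, ...]
    followed: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.candidate_ids)
        if len(self.types) != n or len(self.followed) != n:
            raise ValueError("candidate_ids, types and followed must align")
        for t in self.types:
            if t not in _TYPES:
                raise ValueError(f"unlabeled or unknown candidate type: {t!r}")

    @property
    def k_max(self) -> int:
        return len(self.candidate_ids)

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.k_max:
            raise ValueError(f"K={k} outside the annotated window 1..{self.k_max}")


@dataclass
class EvaluationReport:
    """Per-model, per-K metric record."""

    model: str
    K: int
    P: float = 0.0
    R: float = 0.0
    AP: float = 0.0
    PRSR: float = 0.0
    NSR: float = 0.0
    HSR: float = 0.0
    HLSR: float = 0.0
    PRFRS: float = 0.0
    NFRS: float = 0.0
    HFRS: float = 0.0
    HLFRS: float = 0.0
    PRFRK: float = 0.0
    HLFRK: float = 0.0
    HFRK: float = 0.0
    APHR: float = 0.0
    n_targets: int = 1

    metric_names = ("P", "R", "AP", "PRSR", "NSR", "HSR", "HLSR",
                    "PRFRS", "NFRS", "HFRS", "HLFRS",
                    "PRFRK", "HLFRK", "HFRK", "APHR")


def precision_at_k(lst: AnnotatedRecommendationList, k: int) -> float:
    """Fraction of the top-K suggestions the target would follow."""
    lst._check_k(k)
    return sum(lst.followed[:k]) / k


def recall_at_k(lst: AnnotatedRecommendationList, k: int) -> float:
    """Follows in the top K over all follows in the annotated window.

    0 when nothing was followed at all.
    """
    lst._check_k(k)
    total = sum(lst.followed)
    if total == 0:
        return 0.0
    return sum(lst.followed[:k]) / total


def average_precision(lst: AnnotatedRecommendationList, k: int) -> float:
    """Average precision at K with binary follow relevance.

    Sum of P@i at each followed position i <= K, divided by the number of
    follows within the top K (0 when there are none).
    """
    lst._check_k(k)
    hits = 0
    acc = 0.0
    for i in range(k):
        if lst.followed[i]:
            hits += 1
            acc += hits / (i + 1)
    return acc / hits if hits else 0.0


def type_ratios(lst: AnnotatedRecommendationList, k: int) -> dict[str, float]:
    """Composition ratios of the top-K suggestions.

    Suggested ratios (#type suggested / K), followed-over-suggested ratios
    (#type followed / #type suggested; 0 when the type was never
    suggested), and followed-over-K ratios.  Harmless = neutral +
    pro-recovery.
    """
    lst._check_k(k)
    sug = {t: 0 for t in _TYPES}
    fol = {t: 0 for t in _TYPES}
    for t, f in zip(lst.types[:k], lst.followed[:k]):
        sug[t] += 1
        if f:
            fol[t] += 1
    sug_hl = sug["neutral"] + sug["pro_recovery"]
    fol_hl = fol["neutral"] + fol["pro_recovery"]

    def frs(f: int, s: int) -> float:
        return f / s if s else 0.0

    return {
        "PRSR": sug["pro_recovery"] / k,
        "NSR": sug["neutral"] / k,
        "HSR": sug["harmful"] / k,
        "HLSR": sug_hl / k,
        "PRFRS": frs(fol["pro_recovery"], sug["pro_recovery"]),
        "NFRS": frs(fol["neutral"], sug["neutral"]),
        "HFRS": frs(fol["harmful"], sug["harmful"]),
        "HLFRS": frs(fol_hl, sug_hl),
        "PRFRK": fol["pro_recovery"] / k,
        "HLFRK": fol_hl / k,
        "HFRK": fol["harmful"] / k,
    }


def aphr(ap: float, hlfrk: float) -> float:
    """Harmonic mean of average precision and the harmless-followed ratio.

    0 when both inputs are 0.  At cohort level, pass MAP and the mean
    HLFRK.
    """
    for name, v in (("ap", ap), ("hlfrk", hlfrk)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if ap + hlfrk == 0:
        return 0.0
    return 2.0 * ap * hlfrk / (ap + hlfrk)


def evaluate_list(lst: AnnotatedRecommendationList, k: int,
                  model: str = "model") -> EvaluationReport:
    """Full per-target metric record at one K."""
    ratios = type_ratios(lst, k)
    ap = average_precision(lst, k)
    return EvaluationReport(
        model=model, K=k,
        P=precision_at_k(lst, k), R=recall_at_k(lst, k), AP=ap,
        APHR=aphr(ap, ratios["HLFRK"]), **ratios)


def aggregate_reports(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Cohort-level record: mean of every metric over targets, with APHR
    recomputed from MAP (the mean AP) and the mean HLFRK."""
    if not reports:
        raise ValueError("no reports to aggregate")
    models = {r.model for r in reports}
    ks = {r.K for r in reports}
    if len(models) != 1 or len(ks) != 1:
        raise ValueError("aggregate over a single (model, K) cell")
    n = len(reports)
    agg = EvaluationReport(model=reports[0].model, K=reports[0].K, n_targets=n)
    for name in EvaluationReport.metric_names:
        setattr(agg, name, sum(getattr(r, name) for r in reports) / n)
    agg.APHR = aphr(agg.AP, agg.HLFRK)
    return agg


def round_report(value: float, ndigits: int = 2) -> float:
    """Half-up rounding used only at the reporting layer."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def compare_models(reports: Sequence[EvaluationReport],
                   ndigits: int = 2) -> pd.DataFrame:
    """Tabulate per-(model, K) records and flag the best value per column.

    Returns a DataFrame with one row per (model, K), metrics rounded
    half-up to ``ndigits`` decimals, plus a ``best`` column listing the
    metrics for which that row attains the per-K maximum.
    """
    if not reports:
        raise ValueError("no reports to compare")
    rows = []
    for r in reports:
        row = {"model": r.model, "K": r.K}
        for name in EvaluationReport.metric_names:
            row[name] = round_report(getattr(r, name), ndigits)
        rows.append(row)
    df = pd.DataFrame(rows)
    best_flags = []
    for _, row in df.iterrows():
        sub = df[df["K"] == row["K"]]
        best = [m for m in EvaluationReport.metric_names
                if row[m] == sub[m].max()]
        best_flags.append(",".join(best))
    df["best"] = best_flags
    return df
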