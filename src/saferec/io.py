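"""Readers and writers for the pipeline's plain-text formats.

Edge lists are CSV with a ``follower,followee`` header; accounts are
newline-delimited JSON (one object per line, streamable); interest
matrices, annotations and reports are CSV with header rows.  Everything
is UTF-8 with stable column order, and read/write pairs round-trip
losslessly.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import AnnotatedRecommendationList, EvaluationReport
from .graph import Account, SocialGraph
from .interests import InterestVector
from .ranking import RankedRecommendation

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_csv", "write_edge_csv",
    "read_accounts_jsonl", "write_accounts_jsonl",
    "load_graph",
    "read_interest_csv", "write_interest_csv",
    "read_annotation_csv", "write_annotation_csv",
    "write_recommendations_csv",
    "write_report_csv", "write_report_json",
]

_ACCOUNT_FIELDS = ("id", "label", "texts", "liked_texts", "bio",
                   "is_target", "followee_bios")


def read_edge_csv(path) -> list[tuple[str, str]]:
    """Read a directed edge list; duplicates are dropped with a warning."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dupes = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["follower", "followee"]:
            raise ValueError(f"{path}: expected header 'follower,followee', "
                             f"got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2 or not row[0] or not row[1]:
                raise ValueError(f"{path}: malformed edge row at line {lineno}: {row}")
            edge = (row[0], row[1])
            if edge in seen:
                dupes += 1
                continue
            seen.add(edge)
            edges.append(edge)
    if dupes:
        logger.warning("%s: dropped %d duplicate edge(s)", path, dupes)
    return edges


def write_edge_csv(path, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["follower", "followee"])
        for u, v in sorted(edges):
            writer.writerow([u, v])


def read_accounts_jsonl(path) -> list[Account]:
    """Read account records; missing optional fields get empty defaults."""
    accounts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: invalid JSON at line {lineno}: {exc}") from None
            if "id" not in obj:
                raise ValueError(f"{path}: record at line {lineno} lacks 'id'")
            accounts.append(Account(
                id=obj["id"],
                label=obj.get("label", "unknown"),
                texts=obj.get("texts", []),
                liked_texts=obj.get("liked_texts", []),
                bio=obj.get("bio", ""),
                is_target=bool(obj.get("is_target", False)),
                followee_bios=obj.get("followee_bios", []),
            ))
    return accounts


def write_accounts_jsonl(path, accounts: Iterable[Account]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc in accounts:
            obj = {
                "id": acc.id, "label": acc.label.value, "texts": acc.texts,
                "liked_texts": acc.liked_texts, "bio": acc.bio,
                "is_target": acc.is_target, "followee_bios": acc.followee_bios,
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def load_graph(edges_path, accounts_path) -> SocialGraph:
    """Assemble a SocialGraph from an edge CSV and an account JSONL."""
    accounts = read_accounts_jsonl(accounts_path)
    edges = read_edge_csv(edges_path)
    return SocialGraph(accounts, edges)


def write_interest_csv(path, vectors: Sequence[InterestVector],
                       topics: Sequence[str], which: str = "normalized") -> None:
    rows = []
    for iv in vectors:
        vec = iv.normalized if which == "normalized" else iv.raw
        rows.append({"owner_id": iv.owner_id,
                     **{t: vec[i] for i, t in enumerate(topics)}})
    pd.DataFrame(rows, columns=["owner_id", *topics]).to_csv(path, index=False)


def read_interest_csv(path) -> tuple[list[InterestVector], list[str]]:
    df = pd.read_csv(path)
    topics = [c for c in df.columns if c != "owner_id"]
    vectors = [InterestVector(owner_id=str(row["owner_id"]),
                              raw=np.asarray([row[t] for t in topics], dtype=float))
               for _, row in df.iterrows()]
    return vectors, topics


def write_annotation_csv(path, lists: Sequence[AnnotatedRecommendationList]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_id", "candidate_id", "rank", "type_label", "followed"])
        for lst in lists:
            for rank, (cid, t, f) in enumerate(
                    zip(lst.candidate_ids, lst.types, lst.followed), start=1):
                writer.writerow([lst.target_id, cid, rank, t, int(f)])


def read_annotation_csv(path) -> list[AnnotatedRecommendationList]:
    df = pd.read_csv(path)
    required = {"target_id", "candidate_id", "rank", "type_label", "followed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    lists = []
    for target, sub in df.groupby("target_id", sort=True):
        sub = sub.sort_values("rank")
        lists.append(AnnotatedRecommendationList(
            target_id=str(target),
            candidate_ids=tuple(str(c) for c in sub["candidate_id"]),
            types=tuple(sub["type_label"]),
            followed=tuple(bool(int(f)) for f in sub["followed"])))
    return lists


def write_recommendations_csv(path, target_id: str,
                              recs: Sequence[RankedRecommendation]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "target_id", "candidate_id", "rank_score",
                         "harmlessness", "content_score", "topology_score",
                         "jaccard", "occurrences_ratio", "slot"])
        for rank, r in enumerate(recs, start=1):
            writer.writerow([
                rank, target_id, r.candidate_id,
                f"{r.rank_score:.6f}", f"{r.harmlessness:.6f}",
                f"{r.content_score:.6f}", f"{r.topology_score:.6f}",
                f"{r.jaccard:.6f}", f"{r.occurrences_ratio:.6f}",
                "pro_recovery" if r.is_pro_recovery_slot else "general"])


def write_report_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_report_json(path, reports: Sequence[EvaluationReport]) -> None:
    payload = []
    for r in reports:
        obj = {"model": r.model, "K": r.K, "n_targets": r.n_targets}
        obj.update({name: getattr(r, name) for name in EvaluationReport.metric_names})
        payload.append(obj)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
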