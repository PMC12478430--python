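"""Data model and readers/writers for corpora, queries, click logs, qrels and runs.

File dialects:

* corpus / queries: BEIR-style JSONL — ``{"_id": ..., "title": ..., "text": ...}``
  where ``text`` holds the abstract (queries use ``_id`` / ``text`` only).
* click log: 4-column TSV ``query_id  query_text  doc_id  clicks``.
* qrels: TREC 4-column whitespace file ``query_id  0  doc_id  grade``.
* run: TREC run format ``query_id Q0 doc_id rank score tag``.

All text is UTF-8; whitespace is normalized (runs collapsed, ends stripped)
at read time.  Rankings everywhere are ordered by score descending with ties
broken by doc_id ascending, which makes every output deterministic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

# Qrels: mapping query_id -> {doc_id: integer grade >= 0}
Qrels = dict[str, dict[str, int]]


def normalize_ws(text: str) -> str:
    """Collapse whitespace runs and strip ends."""
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class Document:
    """An article: opaque id, title, abstract (abstract may be empty)."""

    doc_id: str
    title: str
    abstract: str = ""

    def __post_init__(self):
        if not self.title:
            raise ValueError(f"document {self.doc_id!r} has an empty title")

    @property
    def text(self) -> str:
        """Title and abstract joined — the searchable full text."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class Query:
    query_id: str
    text: str

    def __post_init__(self):
        if not normalize_ws(self.text):
            raise ValueError(f"query {self.query_id!r} has empty text")


@dataclass(frozen=True)
class ClickRecord:
    """A (query, document) pair with its aggregated click count c >= 1."""

    query_id: str
    doc_id: str
    clicks: int

    def __post_init__(self):
        if self.clicks < 1:
            raise ValueError(
                f"click count must be >= 1, got {self.clicks} "
                f"for ({self.query_id!r}, {self.doc_id!r})"
            )


class RankedList:
    """An ordered ranking of documents for one query.

    Entries are (doc_id, score) sorted by score descending, ties broken by
    doc_id ascending; duplicate doc_ids are rejected.
    """

    __slots__ = ("query_id", "entries", "meta")

    def __init__(self, query_id: str, entries: Sequence[tuple[str, float]]):
        ids = [d for d, _ in entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate doc_id in ranking for query {query_id!r}")
        self.query_id = query_id
        self.entries = sorted(entries, key=lambda e: (-e[1], e[0]))
        self.meta: dict = {}

    @classmethod
    def from_scores(cls, query_id: str, doc_ids: Sequence[str],
                    scores: Sequence[float], k: int | None = None) -> "RankedList":
        rl = cls(query_id, list(zip(doc_ids, [float(s) for s in scores])))
        if k is not None:
            rl.entries = rl.entries[:k]
        return rl

    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (isinstance(other, RankedList) and self.query_id == other.query_id
                and self.entries == other.entries)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RankedList({self.query_id!r}, {len(self.entries)} docs)"


# ---------------------------------------------------------------- corpus I/O

def read_corpus(path: str | Path) -> list[Document]:
    """Read a BEIR-style JSONL corpus; rejects malformed lines and duplicate ids."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            doc_id = str(obj["_id"])
            if doc_id in seen:
                raise ValueError(f"{path}: duplicate doc_id {doc_id!r} on line {lineno}")
            seen.add(doc_id)
            docs.append(Document(
                doc_id=doc_id,
                title=normalize_ws(str(obj.get("title", ""))),
                abstract=normalize_ws(str(obj.get("text", ""))),
            ))
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps(
                {"_id": d.doc_id, "title": d.title, "text": d.abstract},
                ensure_ascii=False) + "\n")


def read_queries(path: str | Path) -> list[Query]:
    queries: list[Query] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            qid = str(obj["_id"])
            if qid in seen:
                raise ValueError(f"{path}: duplicate query_id {qid!r} on line {lineno}")
            seen.add(qid)
            queries.append(Query(query_id=qid, text=normalize_ws(str(obj["text"]))))
    return queries


def write_queries(queries: Iterable[Query], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in queries:
            fh.write(json.dumps({"_id": q.query_id, "text": q.text},
                                ensure_ascii=False) + "\n")


# -------------------------------------------------------------- click log I/O

def read_click_log(
    path: str | Path,
    corpus: Sequence[Document] | None = None,
) -> tuple[list[ClickRecord], list[Query]]:
    """Read a click-log TSV, aggregating duplicate (query, doc) rows by summing
    clicks and deduplicating queries by id.

    If `corpus` is given, rows whose doc_id is not in the corpus are dropped
    with a logged count.
    """
    known: set[str] | None = {d.doc_id for d in corpus} if corpus is not None else None
    clicks: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    queries: dict[str, Query] = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: expected 4 tab-separated fields on line "
                                 f"{lineno}, got {len(parts)}")
            qid, qtext, doc_id, c_str = parts
            try:
                c = int(c_str)
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer click count on line {lineno}") from exc
            if c < 1:
                raise ValueError(f"{path}: click count {c} < 1 on line {lineno}")
            if known is not None and doc_id not in known:
                dropped += 1
                continue
            if qid not in queries:
                queries[qid] = Query(query_id=qid, text=normalize_ws(qtext))
            key = (qid, doc_id)
            if key not in clicks:
                order.append(key)
            clicks[key] = clicks.get(key, 0) + c
    if dropped:
        logger.warning("read_click_log: dropped %d rows with unknown doc_id", dropped)
    # deterministic order regardless of input row permutation
    records = [ClickRecord(q, d, clicks[(q, d)]) for q, d in sorted(clicks)]
    qlist = [queries[qid] for qid in sorted(queries)]
    return records, qlist


def write_click_log(records: Iterable[ClickRecord],
                    queries: Mapping[str, Query] | Sequence[Query],
                    path: str | Path) -> None:
    if not isinstance(queries, Mapping):
        queries = {q.query_id: q for q in queries}
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.query_id}\t{queries[r.query_id].text}\t{r.doc_id}\t{r.clicks}\n")


# ------------------------------------------------------------------ qrels I/O

def read_qrels(path: str | Path) -> Qrels:
    qrels: Qrels = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: expected 4 whitespace-separated fields "
                                 f"on line {lineno}")
            qid, _iter, doc_id, grade = parts
            g = int(grade)
            if g < 0:
                raise ValueError(f"{path}: negative grade on line {lineno}")
            qrels.setdefault(qid, {})[doc_id] = g
    return qrels


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in sorted(qrels):
            for doc_id in sorted(qrels[qid]):
                fh.write(f"{qid}\t0\t{doc_id}\t{qrels[qid][doc_id]}\n")


# -------------------------------------------------------------------- run I/O

def write_run(ranked_lists: Iterable[RankedList], tag: str, path: str | Path) -> None:
    """Write rankings in TREC run format; empty lists are omitted (logged)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rl in ranked_lists:
            if len(rl) == 0:
                logger.warning("write_run: query %s has an empty ranking, omitted",
                               rl.query_id)
                continue
            for rank, (doc_id, score) in enumerate(rl.entries, start=1):
                fh.write(f"{rl.query_id} Q0 {doc_id} {rank} {score:.6f} {tag}\n")


def read_run(path: str | Path) -> list[RankedList]:
    per_query: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}: expected 6 fields on line {lineno}")
            qid, _q0, doc_id, _rank, score, _tag = parts
            if qid not in per_query:
                per_query[qid] = []
                order.append(qid)
            per_query[qid].append((doc_id, float(score)))
    return [RankedList(qid, per_query[qid]) for qid in order]
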