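"""Ranked-retrieval metrics and embedding-task evaluations.

NDCG@k uses linear gain (trec-eval convention) by default, with the
exponential 2^r - 1 gain available as an option.  MAP@k binarizes relevance
at grade >= 1 and divides by min(R, k) where R is the number of relevant
documents for the query.  Queries with no positively graded document are
excluded from means (logged), matching common trec-eval behavior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Document, Qrels, RankedList
from .encoders import SequenceEncoder, encode_documents, encode_queries

logger = logging.getLogger(__name__)


def _gain(rel: int, kind: str) -> float:
    if kind == "linear":
        return float(rel)
    if kind == "exponential":
        return float(2 ** rel - 1)
    raise ValueError(f"unknown gain kind {kind!r}")


def ndcg_at_k(ranked_list: RankedList, qrels: Qrels, k: int,
              gain: str = "linear") -> float:
    """Normalized discounted cumulative gain over the top k ranks."""
    judgments = qrels.get(ranked_list.query_id)
    if judgments is None:
        raise ValueError(f"query {ranked_list.query_id!r} absent from qrels")
    if not any(g > 0 for g in judgments.values()):
        raise ValueError(f"query {ranked_list.query_id!r} has no positive grades")
    dcg = sum(_gain(judgments.get(doc_id, 0), gain) / math.log2(i + 1)
              for i, (doc_id, _) in enumerate(ranked_list.entries[:k], start=1))
    ideal = sorted(judgments.values(), reverse=True)[:k]
    idcg = sum(_gain(g, gain) / math.log2(i + 1)
               for i, g in enumerate(ideal, start=1))
    return dcg / idcg


def map_at_k(ranked_list: RankedList, qrels: Qrels, k: int) -> float:
    """Average precision over the top k ranks, relevance binarized at grade >= 1."""
    judgments = qrels.get(ranked_list.query_id)
    if judgments is None:
        raise ValueError(f"query {ranked_list.query_id!r} absent from qrels")
    relevant = {d for d, g in judgments.items() if g >= 1}
    if not relevant:
        raise ValueError(f"query {ranked_list.query_id!r} has no positive grades")
    hits = 0
    ap = 0.0
    for i, (doc_id, _) in enumerate(ranked_list.entries[:k], start=1):
        if doc_id in relevant:
            hits += 1
            ap += hits / i
    return ap / min(len(relevant), k)


@dataclass
class MetricReport:
    """Per-query and mean metric values; all values lie in [0, 1]."""

    per_query: dict[str, dict[str, float]]
    mean: dict[str, float]
    query_count: int
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "query_count": self.query_count,
                "skipped": self.skipped, "per_query": self.per_query}


def evaluate_run(
    ranked_lists: Sequence[RankedList],
    qrels: Qrels,
    ndcg_ks: Sequence[int] = (10,),
    map_ks: Sequence[int] = (10,),
    gain: str = "linear",
) -> MetricReport:
    per_query: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    for rl in ranked_lists:
        try:
            row = {f"ndcg@{k}": ndcg_at_k(rl, qrels, k, gain) for k in ndcg_ks}
            row.update({f"map@{k}": map_at_k(rl, qrels, k) for k in map_ks})
        except ValueError as exc:
            logger.warning("evaluate_run: skipping query %s (%s)", rl.query_id, exc)
            skipped.append(rl.query_id)
            continue
        per_query[rl.query_id] = row
    if per_query:
        keys = next(iter(per_query.values())).keys()
        mean = {m: float(np.mean([r[m] for r in per_query.values()])) for m in keys}
    else:
        mean = {}
    return MetricReport(per_query=per_query, mean=mean,
                        query_count=len(per_query), skipped=skipped)


# ------------------------------------------------------- embedding-task evals

def _similarities(qvec: np.ndarray, mat: np.ndarray, kind: str) -> np.ndarray:
    if kind == "inner_product":
        return mat @ qvec
    if kind == "cosine":
        qn = qvec / (np.linalg.norm(qvec) or 1.0)
        mn = mat / np.maximum(np.linalg.norm(mat, axis=1, keepdims=True), 1e-300)
        return mn @ qn
    raise ValueError(f"unknown similarity kind {kind!r}")


def article_similarity_eval(
    query_doc_ids: Sequence[str],
    corpus: Sequence[Document] | Mapping[str, Document],
    doc_encoder: SequenceEncoder,
    qrels: Qrels,
    similarity: str = "inner_product",
    ks: Sequence[int] = (5, 10, 15),
    gain: str = "linear",
) -> MetricReport:
    """Query-by-document evaluation: embed each query article with the
    document encoder and rank its annotated candidate pool by similarity."""
    docs = corpus if isinstance(corpus, Mapping) else {d.doc_id: d for d in corpus}
    ranked: list[RankedList] = []
    for qdoc in query_doc_ids:
        if qdoc not in docs or qdoc not in qrels:
            logger.warning("article_similarity_eval: query article %s missing "
                           "from corpus or qrels; skipped", qdoc)
            continue
        pool = sorted(d for d in qrels[qdoc] if d != qdoc and d in docs)
        if not pool:
            continue
        qvec = encode_documents(doc_encoder,
                                [(docs[qdoc].title, docs[qdoc].abstract)])[0]
        mat = encode_documents(doc_encoder,
                               [(docs[d].title, docs[d].abstract) for d in pool])
        sims = _similarities(qvec, mat, similarity)
        ranked.append(RankedList.from_scores(qdoc, pool, sims))
    return evaluate_run(ranked, qrels, ndcg_ks=ks, map_ks=ks, gain=gain)


def sts_eval(
    sentence_pairs_with_gold: Sequence[tuple[str, str, float]],
    query_encoder: SequenceEncoder,
    similarity: str = "inner_product",
) -> float:
    """Pearson correlation between encoder similarity and gold scores."""
    if len(sentence_pairs_with_gold) < 3:
        raise ValueError("need at least 3 sentence pairs")
    a_texts = [p[0] for p in sentence_pairs_with_gold]
    b_texts = [p[1] for p in sentence_pairs_with_gold]
    gold = np.asarray([p[2] for p in sentence_pairs_with_gold], dtype=np.float64)
    A = encode_queries(query_encoder, a_texts)
    B = encode_queries(query_encoder, b_texts)
    if similarity == "inner_product":
        sims = np.sum(A * B, axis=1)
    elif similarity == "cosine":
        An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
        Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
        sims = np.sum(An * Bn, axis=1)
    else:
        raise ValueError(f"unknown similarity kind {similarity!r}")
    if np.std(gold) == 0 or np.std(sims) == 0:
        raise ValueError("Pearson correlation undefined: zero variance")
    return float(np.corrcoef(sims, gold)[0, 1])
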