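"""Two-stage retrieve-then-rerank inference.

The bi-encoder retriever produces the top-K candidates by exact inner
product; the cross-encoder rescores those candidates and the final ranking
is by cross-encoder score (ties doc_id ascending), truncated to final_k.
Retriever scores are retained in the result's metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus_io import Document, Query, RankedList
from .encoders import (CrossEncoderScorer, SequenceEncoder, encode_queries,
                       score_pairs)
from .index import DenseIndex, search_batch

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    first_stage_k: int = 100     # candidates handed to the re-ranker
    final_k: int = 10
    similarity: str = "inner_product"

    def __post_init__(self):
        if self.first_stage_k < 1:
            raise ValueError("first_stage_k must be >= 1")
        if self.final_k > self.first_stage_k:
            raise ValueError("final_k must be <= first_stage_k")


def retrieve_rerank(
    query: Query,
    index: DenseIndex,
    query_encoder: SequenceEncoder,
    scorer: CrossEncoderScorer | Callable[[str, str], float],
    corpus: Mapping[str, Document],
    config: PipelineConfig = PipelineConfig(),
) -> RankedList:
    return retrieve_rerank_all([query], index, query_encoder, scorer,
                               corpus, config)[0]


def retrieve_rerank_all(
    queries: Sequence[Query],
    index: DenseIndex,
    query_encoder: SequenceEncoder,
    scorer: CrossEncoderScorer | Callable[[str, str], float],
    corpus: Mapping[str, Document] | Sequence[Document],
    config: PipelineConfig = PipelineConfig(),
    score_batch_size: int = 256,
) -> list[RankedList]:
    """Run the two-stage pipeline for a batch of queries."""
    docs = corpus if isinstance(corpus, Mapping) else {d.doc_id: d for d in corpus}
    k = config.first_stage_k
    if k > index.size:
        logger.warning("retrieve_rerank: first_stage_k=%d exceeds index size %d; "
                       "clamped", k, index.size)
        k = index.size
    qvecs = encode_queries(query_encoder, [q.text for q in queries])
    first = search_batch(index, qvecs, k, [q.query_id for q in queries])

    # second-stage rescoring, batched across queries; `scorer` is either a
    # cross-encoder or any callable (query_id, doc_id) -> score (e.g. an
    # oracle in tests)
    if callable(scorer) and not hasattr(scorer, "forward"):
        ce_scores = np.asarray([scorer(q.query_id, doc_id)
                                for q, rl in zip(queries, first)
                                for doc_id, _ in rl.entries], dtype=np.float64)
    else:
        triples: list[tuple[str, str, str]] = []
        for q, rl in zip(queries, first):
            for doc_id, _ in rl.entries:
                d = docs[doc_id]
                triples.append((q.text, d.title, d.abstract))
        ce_scores = np.concatenate([
            score_pairs(scorer, triples[i:i + score_batch_size])
            for i in range(0, len(triples), score_batch_size)
        ]) if triples else np.empty(0)

    out: list[RankedList] = []
    off = 0
    for q, rl in zip(queries, first):
        n = len(rl.entries)
        scores = ce_scores[off:off + n]
        off += n
        final = RankedList.from_scores(q.query_id, rl.doc_ids(), scores,
                                       k=config.final_k)
        final.meta["retriever_scores"] = {d: s for d, s in rl.entries}
        out.append(final)
    return out


def retrieve_only(
    queries: Sequence[Query],
    index: DenseIndex,
    query_encoder: SequenceEncoder,
    k: int,
) -> list[RankedList]:
    """First-stage retrieval without re-ranking."""
    qvecs = encode_queries(query_encoder, [q.text for q in queries])
    return search_batch(index, qvecs, min(k, index.size),
                        [q.query_id for q in queries])
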