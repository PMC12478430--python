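"""Retriever training: inner-product relevance, click-weighted bidirectional
in-batch contrastive loss, and the gradient-descent training loop.

Each training instance is a (query q_i, clicked document d_i, click count
c_i) triple.  Within a mini-batch of |B| instances the other |B|-1 documents
serve as negatives for q_i (query-to-document direction) and the other
queries as negatives for d_i (document-to-query direction):

    L_i^q2d = -log softmax_i( E(q_i)^T E(d_m), m=1..|B| )
    L_i^d2q = -log softmax_i( E(q_m)^T E(d_i), m=1..|B| )

Instance losses are weighted by normalized log-clicks
w_i = log2(c_i + 1) / sum_k log2(c_k + 1), and the two directions are mixed
as L_B = lambda * L_B^q2d + (1 - lambda) * L_B^d2q (lambda = 0.5 by
default).  Raw inner products are used — no temperature, no normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor
from .corpus_io import ClickRecord, Document, Query
from .encoders import SequenceEncoder, build_doc_ids, build_query_ids
from .optim import Adam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    steps: int = 1000
    learning_rate: float = 1e-4
    seed: int = 0
    loss_mix: float = 0.5          # lambda: weight of the q2d direction
    mask_duplicates: bool = False  # mask same-doc collisions out of negatives

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.loss_mix <= 1.0:
            raise ValueError("loss_mix must be in [0, 1]")


@dataclass
class TrainResult:
    loss_trace: list[float]

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def relevance(query_vec: np.ndarray, doc_vec: np.ndarray) -> float:
    """Rel(q, d) = E(q)^T E(d): raw inner product, no normalization."""
    q = np.asarray(query_vec, dtype=np.float64)
    d = np.asarray(doc_vec, dtype=np.float64)
    if q.shape != d.shape or q.ndim != 1:
        raise ValueError(f"dimension mismatch: {q.shape} vs {d.shape}")
    return float(q @ d)


def click_weights(clicks: Sequence[int]) -> np.ndarray:
    """w_i = log2(c_i + 1) / sum_k log2(c_k + 1); positive, sums to 1."""
    c = np.asarray(clicks, dtype=np.float64)
    if c.size == 0:
        raise ValueError("clicks must be non-empty")
    if np.any(c < 1):
        raise ValueError(f"all click counts must be >= 1, got {clicks}")
    lw = np.log2(c + 1.0)
    return lw / lw.sum()


def contrastive_batch_loss(
    query_vecs,
    doc_vecs,
    clicks: Sequence[int],
    loss_mix: float = 0.5,
    mask_duplicates: bool = False,
    doc_ids: Sequence[str] | None = None,
):
    """Click-weighted bidirectional in-batch contrastive loss.

    Accepts numpy arrays (returns float) or autograd Tensors (returns a
    scalar Tensor for backprop).  Log-sum-exp stabilized.
    """
    tensor_in = isinstance(query_vecs, Tensor)
    Q = query_vecs if tensor_in else Tensor(np.asarray(query_vecs, dtype=np.float64))
    D = doc_vecs if tensor_in else Tensor(np.asarray(doc_vecs, dtype=np.float64))
    if Q.shape != D.shape:
        raise ValueError(f"query/document count or width mismatch: "
                         f"{Q.shape} vs {D.shape}")
    B = Q.shape[0]
    if len(clicks) != B:
        raise ValueError("clicks not aligned with embeddings")
    if not (np.all(np.isfinite(Q.data)) and np.all(np.isfinite(D.data))):
        raise ValueError("non-finite embedding values")
    w = Tensor(click_weights(clicks))

    S = Q @ D.swapaxes(0, 1)                       # (B, B) similarity matrix
    if mask_duplicates and doc_ids is not None:
        ids = np.asarray(doc_ids)
        dup = (ids[:, None] == ids[None, :]) & ~np.eye(B, dtype=bool)
        S = S + Tensor(np.where(dup, -1e9, 0.0))
    eye = Tensor(np.eye(B))
    diag = (S * eye).sum(axis=1)                   # Rel(q_i, d_i)
    l_q2d = S.logsumexp(axis=1) - diag
    l_d2q = S.logsumexp(axis=0) - diag
    loss = ((w * l_q2d).sum() * loss_mix
            + (w * l_d2q).sum() * (1.0 - loss_mix))
    return loss if tensor_in else float(loss.data)


def train_retriever(
    pairs: Sequence[ClickRecord],
    corpus: Sequence[Document] | Mapping[str, Document],
    queries: Sequence[Query] | Mapping[str, Query],
    query_encoder: SequenceEncoder,
    doc_encoder: SequenceEncoder,
    config: TrainConfig,
) -> TrainResult:
    """Train the two towers on click pairs with in-batch negatives.

    Deterministic given config.seed: pair order is canonicalized, shuffling
    and batching are driven by a seeded generator.
    """
    if not pairs:
        raise ValueError("no training pairs")
    docs = corpus if isinstance(corpus, Mapping) else {d.doc_id: d for d in corpus}
    qmap = queries if isinstance(queries, Mapping) else {q.query_id: q for q in queries}
    pairs = sorted(pairs, key=lambda r: (r.query_id, r.doc_id))

    # tokenize once
    q_seqs = {qid: build_query_ids(query_encoder.tokenizer, qmap[qid].text,
                                   query_encoder.config)
              for qid in {p.query_id for p in pairs}}
    d_seqs = {did: build_doc_ids(doc_encoder.tokenizer, docs[did].title,
                                 docs[did].abstract, doc_encoder.config)
              for did in {p.doc_id for p in pairs}}

    # deduplicate by identity so shared tensors (e.g. a tied embedding
    # table) receive a single optimizer update per step
    all_params: dict[str, Tensor] = {}
    seen_ids: set[int] = set()
    for prefix, enc in (("q", query_encoder), ("d", doc_encoder)):
        for k, v in enc.params.items():
            if id(v) not in seen_ids:
                seen_ids.add(id(v))
                all_params[f"{prefix}.{k}"] = v
    opt = Adam(all_params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    order = rng.permutation(len(pairs))
    cursor = 0
    trace: list[float] = []
    for step in range(config.steps):
        if cursor + config.batch_size > len(pairs):
            order = rng.permutation(len(pairs))
            cursor = 0
        batch = [pairs[i] for i in order[cursor:cursor + config.batch_size]]
        cursor += config.batch_size

        Q = query_encoder.forward([q_seqs[p.query_id] for p in batch])
        D = doc_encoder.forward([d_seqs[p.doc_id] for p in batch])
        loss = contrastive_batch_loss(
            Q, D, [p.clicks for p in batch], config.loss_mix,
            config.mask_duplicates, [p.doc_id for p in batch])
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if (step + 1) % 200 == 0:
            logger.info("retriever step %d/%d loss=%.4f",
                        step + 1, config.steps, trace[-1])
    return TrainResult(loss_trace=trace)
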