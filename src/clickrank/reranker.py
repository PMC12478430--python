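"""Cross-encoder re-ranker training with local hard negatives.

Local negatives are sampled from a rank window [e, f] of the frozen,
pre-trained retriever's own results (via exact MIPS), so the re-ranker
trains on the candidate distribution it will face at inference.  Each
training instance is a query, its clicked (positive) document, and M
sampled non-clicked window documents; the loss is a negative
log-likelihood over the M+1 cross-encoder scores:

    L_i = -log[ exp(s_i^+) / (exp(s_i^+) + sum_j exp(s_ij^-)) ]

Mini-batch losses are weighted sums of instance losses; by default the
weights reuse the retriever's normalized log2(clicks + 1) formula on the
positive's click count (an ``unweighted`` switch disables this).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor, concatenate
from .corpus_io import ClickRecord, Document, Query
from .encoders import CrossEncoderScorer, build_joint_ids
from .index import DenseIndex, search_batch
from .encoders import SequenceEncoder, encode_queries
from .optim import Adam
from .retriever import TrainConfig, TrainResult, click_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiningConfig:
    """Rank window [e, f] is 1-based and inclusive; M negatives per instance."""

    e: int = 31
    f: int = 100
    m: int = 7
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.e <= self.f:
            raise ValueError(f"need 1 <= e <= f, got e={self.e}, f={self.f}")
        if self.m < 0:
            raise ValueError("M must be >= 0")


@dataclass(frozen=True)
class RerankerInstance:
    query_id: str
    query_text: str
    pos_doc_id: str
    neg_doc_ids: tuple[str, ...]
    clicks: int

    def __post_init__(self):
        if self.pos_doc_id in self.neg_doc_ids:
            raise ValueError(f"positive {self.pos_doc_id!r} appears among negatives")
        if self.clicks < 1:
            raise ValueError("clicks must be >= 1")


def mine_local_negatives(
    pairs: Sequence[ClickRecord],
    queries: Sequence[Query] | Mapping[str, Query],
    index: DenseIndex,
    query_encoder: SequenceEncoder,
    config: MiningConfig,
) -> list[RerankerInstance]:
    """For each (q, d+) pair: retrieve top-f, take ranks e..f minus all of
    q's clicked documents, and sample M negatives without replacement.

    Instances whose candidate pool is smaller than M are dropped (logged).
    Deterministic given config.seed.
    """
    qmap = queries if isinstance(queries, Mapping) else {q.query_id: q for q in queries}
    f = config.f
    if f > index.size:
        logger.warning("mine_local_negatives: f=%d exceeds index size %d; clamped",
                       f, index.size)
        f = index.size
    e = min(config.e, f)

    clicked_of: dict[str, set[str]] = {}
    for p in pairs:
        clicked_of.setdefault(p.query_id, set()).add(p.doc_id)

    pairs = sorted(pairs, key=lambda r: (r.query_id, r.doc_id))
    qids = sorted(clicked_of)
    qvecs = encode_queries(query_encoder, [qmap[q].text for q in qids])
    ranked = {qid: rl.doc_ids()
              for qid, rl in zip(qids, search_batch(index, qvecs, f, qids))}

    rng = np.random.default_rng(config.seed)
    out: list[RerankerInstance] = []
    dropped = 0
    for p in pairs:
        window = ranked[p.query_id][e - 1:f]
        pool = [d for d in window if d not in clicked_of[p.query_id]]
        if len(pool) < config.m:
            dropped += 1
            continue
        negs = ([] if config.m == 0 else
                [pool[i] for i in sorted(rng.choice(len(pool), size=config.m,
                                                    replace=False))])
        out.append(RerankerInstance(
            query_id=p.query_id, query_text=qmap[p.query_id].text,
            pos_doc_id=p.doc_id, neg_doc_ids=tuple(negs), clicks=p.clicks))
    if dropped:
        logger.warning("mine_local_negatives: dropped %d instances with fewer "
                       "than M=%d candidates in window [%d, %d]",
                       dropped, config.m, e, f)
    return out


def nll_from_scores(scores) -> Tensor | float:
    """NLL of the positive given scores [s+, s1-, ..., sM-]; stabilized."""
    tensor_in = isinstance(scores, Tensor)
    s = scores if tensor_in else Tensor(np.asarray(scores, dtype=np.float64))
    if not np.all(np.isfinite(s.data)):
        raise ValueError("non-finite scores")
    loss = s.logsumexp(axis=0) - s[0]
    return loss if tensor_in else float(loss.data)


def reranker_instance_loss(
    scorer: CrossEncoderScorer,
    instance: RerankerInstance,
    corpus: Mapping[str, Document],
) -> float:
    """Evaluate the instance NLL with the given cross-encoder."""
    docs = [corpus[instance.pos_doc_id]] + [corpus[d] for d in instance.neg_doc_ids]
    seqs = [build_joint_ids(scorer.tokenizer, instance.query_text,
                            d.title, d.abstract, scorer.config) for d in docs]
    scores = scorer.forward(seqs).reshape((len(docs),))
    return float(nll_from_scores(scores).data)


def train_reranker(
    instances: Sequence[RerankerInstance],
    scorer: CrossEncoderScorer,
    corpus: Sequence[Document] | Mapping[str, Document],
    config: TrainConfig,
    unweighted: bool = False,
) -> TrainResult:
    """Train the cross-encoder on mined instances.

    Per mini-batch: loss = sum_i w_i L_i, with w_i the normalized
    log2(clicks+1) weights of the positives (uniform if ``unweighted``).
    """
    if not instances:
        raise ValueError("no training instances")
    docs = corpus if isinstance(corpus, Mapping) else {d.doc_id: d for d in corpus}
    instances = sorted(instances,
                       key=lambda r: (r.query_id, r.pos_doc_id, r.neg_doc_ids))

    seq_cache: dict[tuple[str, str], list[int]] = {}

    def joint_seq(inst: RerankerInstance, doc_id: str) -> list[int]:
        key = (inst.query_id, doc_id)
        if key not in seq_cache:
            d = docs[doc_id]
            seq_cache[key] = build_joint_ids(scorer.tokenizer, inst.query_text,
                                             d.title, d.abstract, scorer.config)
        return seq_cache[key]

    opt = Adam(scorer.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(instances))
    cursor = 0
    trace: list[float] = []
    for step in range(config.steps):
        if cursor + config.batch_size > len(instances):
            order = rng.permutation(len(instances))
            cursor = 0
        batch = [instances[i] for i in order[cursor:cursor + config.batch_size]]
        cursor += config.batch_size

        seqs: list[list[int]] = []
        sizes: list[int] = []
        for inst in batch:
            group = [joint_seq(inst, inst.pos_doc_id)] + \
                    [joint_seq(inst, d) for d in inst.neg_doc_ids]
            seqs.extend(group)
            sizes.append(len(group))
        all_scores = scorer.forward(seqs).reshape((len(seqs),))

        losses = []
        off = 0
        for n in sizes:
            losses.append(nll_from_scores(all_scores[off:off + n]).reshape((1,)))
            off += n
        l_vec = concatenate(losses, axis=0)
        if unweighted:
            w = np.full(len(batch), 1.0 / len(batch))
        else:
            w = click_weights([inst.clicks for inst in batch])
        loss = (l_vec * Tensor(w)).sum()

        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if (step + 1) % 200 == 0:
            logger.info("reranker step %d/%d loss=%.4f",
                        step + 1, config.steps, trace[-1])
    return TrainResult(loss_trace=trace)


# -------------------------------------------------------------- instance I/O

def write_instances(instances: Sequence[RerankerInstance],
                    path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in instances:
            fh.write(json.dumps({
                "query_id": r.query_id, "query_text": r.query_text,
                "pos": r.pos_doc_id, "negs": list(r.neg_doc_ids),
                "clicks": r.clicks}, ensure_ascii=False) + "\n")


def read_instances(path: str | Path) -> list[RerankerInstance]:
    out: list[RerankerInstance] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            o = json.loads(line)
            out.append(RerankerInstance(
                query_id=o["query_id"], query_text=o["query_text"],
                pos_doc_id=o["pos"], neg_doc_ids=tuple(o["negs"]),
                clicks=int(o["clicks"])))
    return out
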