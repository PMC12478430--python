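"""High-level training stages with the package's default configurations.

These are the entry points the CLI and the experiment scripts use; each is
a thin composition of the lower-level modules with defaults chosen for the
desk-scale synthetic worlds (tiny from-scratch encoders, minutes on one
CPU):

* retriever towers: position-gated bag-of-embeddings encoders (h=64, two
  dense layers), Adam 1e-2, batch 32, 2000 steps — from-scratch training
  needs a far larger step size than fine-tuning a pretrained model would;
* cross-encoder: 2-layer transformer (h=64) initialized from the trained
  document tower (frozen norm-equalized embeddings, identity attention),
  Adam 1e-3, batch 16, 600 steps.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .corpus_io import ClickRecord, Document, Query
from .encoders import (CrossEncoderScorer, EncoderConfig, SequenceEncoder,
                       Tokenizer, init_reranker_from_retriever,
                       make_bi_encoder)
from .index import DenseIndex, build_index
from .reranker import (MiningConfig, RerankerInstance, mine_local_negatives,
                       train_reranker)
from .retriever import TrainConfig, TrainResult, train_retriever

#: Default encoder/training settings for the two stages.
RETRIEVER_ENCODER = EncoderConfig(arch="bag", hidden_size=64, n_layers=2)
RERANKER_ENCODER = EncoderConfig(arch="transformer", hidden_size=64, n_layers=2)
RETRIEVER_TRAINING = TrainConfig(batch_size=32, steps=2000, learning_rate=1e-2)
RERANKER_TRAINING = TrainConfig(batch_size=16, steps=600, learning_rate=1e-3)


def build_tokenizer(corpus: Sequence[Document],
                    queries: Sequence[Query]) -> Tokenizer:
    return Tokenizer.from_texts([d.text for d in corpus]
                                + [q.text for q in queries])


def fit_retriever(
    pairs: Sequence[ClickRecord],
    corpus: Sequence[Document],
    queries: Sequence[Query],
    seed: int,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    share_embeddings: bool = False,
    tokenizer: Tokenizer | None = None,
) -> tuple[SequenceEncoder, SequenceEncoder, TrainResult]:
    """Train the bi-encoder retriever end to end; returns (QEnc, DEnc, trace)."""
    tok = tokenizer or build_tokenizer(corpus, queries)
    enc_cfg = encoder_config or EncoderConfig(
        **{**RETRIEVER_ENCODER.__dict__, "seed": seed})
    tr_cfg = train_config or TrainConfig(
        **{**RETRIEVER_TRAINING.__dict__, "seed": seed})
    q_enc, d_enc = make_bi_encoder(enc_cfg, tok, share_embeddings)
    result = train_retriever(pairs, corpus, queries, q_enc, d_enc, tr_cfg)
    return q_enc, d_enc, result


def fit_reranker(
    pairs: Sequence[ClickRecord],
    corpus: Sequence[Document],
    queries: Sequence[Query],
    query_encoder: SequenceEncoder,
    doc_encoder: SequenceEncoder,
    index: DenseIndex,
    seed: int,
    mining_config: MiningConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    unweighted: bool = False,
) -> tuple[CrossEncoderScorer, list[RerankerInstance], TrainResult]:
    """Mine local negatives from the frozen retriever and train the
    cross-encoder on them; returns (scorer, instances, trace)."""
    m_cfg = mining_config or MiningConfig(seed=seed)
    instances = mine_local_negatives(pairs, queries, index, query_encoder, m_cfg)
    enc_cfg = encoder_config or EncoderConfig(
        **{**RERANKER_ENCODER.__dict__, "seed": seed})
    tr_cfg = train_config or TrainConfig(
        **{**RERANKER_TRAINING.__dict__, "seed": seed})
    scorer = CrossEncoderScorer(enc_cfg, doc_encoder.tokenizer)
    init_reranker_from_retriever(scorer, doc_encoder)
    result = train_reranker(instances, scorer, corpus, tr_cfg,
                            unweighted=unweighted)
    return scorer, instances, result
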