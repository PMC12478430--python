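"""Synthetic click-log worlds with planted topical relevance.

The generator emulates the statistical structure that click-log training
assumes: a corpus of articles clustered into topics with disjoint core
vocabularies plus shared background tokens; queries that target one topic;
click counts that grow with true relevance; a configurable fraction of
"keyword" queries (single-token, or an exact phrase injected verbatim into
every clicked article) versus "non-keyword" queries; and optional spurious
cross-topic noise clicks.

Tokens are fixed-width pseudo-words (``w00042``) so that substring matching
in the keyword filter behaves exactly like token matching.  Everything is
deterministic given the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import (ClickRecord, Document, Qrels, Query, write_click_log,
                        write_corpus, write_qrels, write_queries)
from .filtering import QueryClass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic retrieval world.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 20 topics x 100 documents x 10 queries over a 5000-token
    vocabulary, which trains in minutes on one CPU.
    """

    n_topics: int = 20
    vocab_size: int = 5000
    docs_per_topic: int = 100
    queries_per_topic: int = 10
    keyword_fraction: float = 0.5
    click_noise_rate: float = 0.05
    click_scale: float = 2.0
    seed: int = 0
    # corpus shape
    core_size: int = 40           # disjoint topic-core vocabulary per topic
    min_background: int = 200     # shared background pool
    title_len: int = 4
    abstract_len: int = 26
    core_rate: float = 0.7        # P(token drawn from topic core)
    clicked_per_query: int = 5    # designated clicked subset (qrels grade 2)

    def __post_init__(self):
        for name in ("n_topics", "vocab_size", "docs_per_topic",
                     "queries_per_topic", "core_size", "clicked_per_query"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("keyword_fraction", "click_noise_rate", "core_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.click_scale <= 0:
            raise ValueError("click_scale must be > 0")
        needed = self.n_topics * self.core_size + self.min_background
        if self.vocab_size < needed:
            raise ValueError(
                f"vocab_size={self.vocab_size} too small for {self.n_topics} "
                f"disjoint topic cores of {self.core_size} tokens plus "
                f"{self.min_background} background tokens; need >= {needed}")


@dataclass
class World:
    """A generated world: corpus + queries + click log + ground truth."""

    spec: WorldSpec
    corpus: list[Document]
    queries: list[Query]
    click_log: list[ClickRecord]
    qrels: Qrels
    query_topic: dict[str, int]
    query_class: dict[str, QueryClass]
    doc_topic: dict[str, int]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus(self.corpus, out / "corpus.jsonl")
        write_queries(self.queries, out / "queries.jsonl")
        write_click_log(self.click_log, self.queries, out / "clicks.tsv")
        write_qrels(self.qrels, out / "qrels.tsv")
        with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
            for q in self.queries:
                fh.write(f"{q.query_id}\t{self.query_topic[q.query_id]}\t"
                         f"{self.query_class[q.query_id].value}\n")


def _word(i: int) -> str:
    return f"w{i:05d}"


def generate_world(spec: WorldSpec) -> World:
    """Generate a full synthetic world, byte-reproducible from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    cores = [np.arange(t * spec.core_size, (t + 1) * spec.core_size)
             for t in range(spec.n_topics)]
    background = np.arange(spec.n_topics * spec.core_size, spec.vocab_size)

    def sample_tokens(topic: int, n: int) -> list[str]:
        from_core = rng.random(n) < spec.core_rate
        ids = np.where(from_core,
                       rng.choice(cores[topic], size=n),
                       rng.choice(background, size=n))
        return [_word(int(i)) for i in ids]

    # ---- documents (abstracts kept as mutable token lists for injection)
    doc_ids: list[str] = []
    titles: dict[str, list[str]] = {}
    abstracts: dict[str, list[str]] = {}
    doc_topic: dict[str, int] = {}
    docs_of_topic: dict[int, list[str]] = {t: [] for t in range(spec.n_topics)}
    for t in range(spec.n_topics):
        for j in range(spec.docs_per_topic):
            did = f"d{t:03d}_{j:04d}"
            doc_ids.append(did)
            titles[did] = sample_tokens(t, spec.title_len)
            abstracts[did] = sample_tokens(t, spec.abstract_len)
            doc_topic[did] = t
            docs_of_topic[t].append(did)

    # ---- queries, clicks, qrels
    queries: list[Query] = []
    click_log: list[ClickRecord] = []
    qrels: Qrels = {}
    query_topic: dict[str, int] = {}
    query_class: dict[str, QueryClass] = {}
    for t in range(spec.n_topics):
        for j in range(spec.queries_per_topic):
            qid = f"q{t:03d}_{j:04d}"
            clicked = [str(d) for d in rng.choice(
                docs_of_topic[t], size=min(spec.clicked_per_query,
                                           spec.docs_per_topic), replace=False)]
            is_kw = rng.random() < spec.keyword_fraction
            if is_kw and rng.random() < 0.5:
                # single-token keyword query
                qtext = _word(int(rng.choice(cores[t])))
            elif is_kw:
                # exact-phrase keyword query: inject the phrase verbatim into
                # every clicked article's abstract
                phrase = [_word(int(i)) for i in
                          rng.choice(cores[t], size=2, replace=False)]
                qtext = " ".join(phrase)
                for did in clicked:
                    abstracts[did] = abstracts[did] + phrase
            else:
                qtext = " ".join(
                    _word(int(i)) for i in
                    rng.choice(cores[t], size=3, replace=False))
            queries.append(Query(query_id=qid, text=qtext))
            query_topic[qid] = t
            query_class[qid] = QueryClass.KEYWORD if is_kw else QueryClass.NON_KEYWORD

            qrels[qid] = {did: 1 for did in docs_of_topic[t]}
            for did in clicked:
                qrels[qid][did] = 2
                c = 1 + int(rng.poisson(spec.click_scale * 2))
                click_log.append(ClickRecord(qid, did, c))
            if rng.random() < spec.click_noise_rate:
                other = [x for x in range(spec.n_topics) if x != t]
                if other:
                    ot = int(rng.choice(other))
                    noise_doc = str(rng.choice(docs_of_topic[ot]))
                    if noise_doc not in {r.doc_id for r in click_log
                                         if r.query_id == qid}:
                        click_log.append(ClickRecord(qid, noise_doc, 1))

    corpus = [Document(doc_id=did,
                       title=" ".join(titles[did]),
                       abstract=" ".join(abstracts[did]))
              for did in doc_ids]
    return World(spec=spec, corpus=corpus, queries=queries, click_log=click_log,
                 qrels=qrels, query_topic=query_topic, query_class=query_class,
                 doc_topic=doc_topic)


def holdout_split(
    queries: Sequence[Query],
    fraction: float,
    seed: int,
    query_topic: Mapping[str, int],
) -> tuple[list[Query], list[Query]]:
    """Deterministic topic-stratified train/test split of queries."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    by_topic: dict[int, list[Query]] = {}
    for q in queries:
        by_topic.setdefault(query_topic[q.query_id], []).append(q)
    rng = np.random.default_rng(seed)
    train: list[Query] = []
    test: list[Query] = []
    for t in sorted(by_topic):
        qs = sorted(by_topic[t], key=lambda q: q.query_id)
        if len(qs) < 2:
            raise ValueError(f"topic {t} has fewer than 2 queries; cannot split")
        n_test = int(round(fraction * len(qs)))
        n_test = min(max(n_test, 1), len(qs) - 1)
        perm = rng.permutation(len(qs))
        test.extend(qs[i] for i in sorted(perm[:n_test]))
        train.extend(qs[i] for i in sorted(perm[n_test:]))
    return train, test


def article_similarity_task(
    world: World,
    queries_per_topic: int = 2,
    pool_size: int = 30,
    positives_per_pool: int = 10,
    seed: int = 0,
) -> tuple[list[str], Qrels]:
    """Build a query-by-document similarity task: each query article gets an
    annotated candidate pool of same-topic (relevant) and cross-topic
    (irrelevant) articles."""
    rng = np.random.default_rng(seed)
    spec = world.spec
    docs_of_topic: dict[int, list[str]] = {}
    for did, t in world.doc_topic.items():
        docs_of_topic.setdefault(t, []).append(did)
    query_docs: list[str] = []
    qrels: Qrels = {}
    all_topics = sorted(docs_of_topic)
    for t in all_topics:
        pool_t = sorted(docs_of_topic[t])
        picked = rng.choice(pool_t, size=min(queries_per_topic, len(pool_t)),
                            replace=False)
        for qdoc in picked:
            qdoc = str(qdoc)
            same = [d for d in pool_t if d != qdoc]
            pos = [str(d) for d in rng.choice(
                same, size=min(positives_per_pool, len(same)), replace=False)]
            n_neg = max(pool_size - len(pos), 0)
            other_docs = [d for tt in all_topics if tt != t
                          for d in docs_of_topic[tt]]
            neg = [str(d) for d in rng.choice(
                sorted(other_docs), size=min(n_neg, len(other_docs)),
                replace=False)]
            query_docs.append(qdoc)
            qrels[qdoc] = {**{d: 1 for d in pos}, **{d: 0 for d in neg}}
    return query_docs, qrels


def sts_task(
    world: World, n_pairs: int = 100, seed: int = 0, sentence_len: int = 5,
) -> list[tuple[str, str, float]]:
    """Sentence pairs with gold similarity = count of shared tokens.

    Half the pairs share a topic (high overlap), half cross topics
    (overlap ~ 0), giving a graded gold scale."""
    rng = np.random.default_rng(seed)
    spec = world.spec
    cores = [np.arange(t * spec.core_size, (t + 1) * spec.core_size)
             for t in range(spec.n_topics)]
    pairs: list[tuple[str, str, float]] = []
    for i in range(n_pairs):
        t1 = int(rng.integers(spec.n_topics))
        same = i % 2 == 0 and spec.n_topics > 1
        t2 = t1 if same or spec.n_topics == 1 else int(
            rng.choice([x for x in range(spec.n_topics) if x != t1]))
        a = [int(x) for x in rng.choice(cores[t1], size=sentence_len, replace=False)]
        if same:
            n_shared = int(rng.integers(1, sentence_len + 1))
            b = a[:n_shared] + [int(x) for x in rng.choice(
                [c for c in cores[t2] if c not in a],
                size=sentence_len - n_shared, replace=False)]
        else:
            b = [int(x) for x in rng.choice(cores[t2], size=sentence_len,
                                            replace=False)]
        gold = float(len(set(a) & set(b)))
        pairs.append((" ".join(_word(x) for x in a),
                      " ".join(_word(x) for x in b), gold))
    return pairs
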