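"""Click-log query filtering.

Splits an aggregated click log into two training sets:

* retriever pairs — every pair whose query is informational (not navigational);
* re-ranker pairs — the subset whose query is *non-keyword*, i.e. needs
  semantic rather than lexical matching.

A query is a **keyword query** when it has a single whitespace token, or when
every clicked article contains the whole query verbatim (case-insensitive
contiguous substring of title + " " + abstract, after whitespace
normalization).  Everything else among the informational queries is
non-keyword.

Navigational queries (author / field-tag lookups) are in production detected
by a dedicated classifier external to this package; here a transparent
regex-based stub is shipped, and any user-supplied predicate can replace it.
"""

from __future__ import annotations

import logging
import re
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from .corpus_io import ClickRecord, Document, Query, normalize_ws

logger = logging.getLogger(__name__)


class QueryClass(Enum):
    NAVIGATIONAL = "navigational"
    KEYWORD = "keyword"
    NON_KEYWORD = "non_keyword"


#: Default navigational patterns: author-style "surname initials [year]" and
#: queries carrying bracketed PubMed field tags like [au], [ti], [journal].
DEFAULT_NAV_PATTERNS: tuple[str, ...] = (
    r"^[a-z][a-z\-']+ [a-z]{1,2}(?: \d{4})?$",   # "smith j", "smith jr 2021"
    r"\[[a-z]{2,10}\]",                           # "...[au]", "...[journal]"
)


def is_navigational(
    query: Query | str,
    patterns: Sequence[str] | None = None,
    predicate: Callable[[str], bool] | None = None,
) -> bool:
    """Rule-based navigational-query stub; `predicate` overrides entirely."""
    text = query.text if isinstance(query, Query) else query
    text = normalize_ws(text)
    if not text:
        raise ValueError("query text is empty")
    if predicate is not None:
        return bool(predicate(text))
    pats = DEFAULT_NAV_PATTERNS if patterns is None else patterns
    low = text.lower()
    return any(re.search(p, low) for p in pats)


def is_keyword_query(query: Query | str, clicked_documents: Sequence[Document]) -> bool:
    """True iff the query has one whitespace token, or every clicked document
    contains the whole query as a case-insensitive contiguous substring of
    title + " " + abstract."""
    if not clicked_documents:
        raise ValueError("keyword classification is undefined without clicked documents")
    text = normalize_ws(query.text if isinstance(query, Query) else query)
    # split on Unicode whitespace only, so hyphenated terms stay one word
    if len(text.split()) == 1:
        return True
    needle = text.lower()
    return all(needle in normalize_ws(d.text).lower() for d in clicked_documents)


def classify_query(
    query: Query | str,
    clicked_documents: Sequence[Document],
    nav_patterns: Sequence[str] | None = None,
    nav_predicate: Callable[[str], bool] | None = None,
) -> QueryClass:
    if is_navigational(query, nav_patterns, nav_predicate):
        return QueryClass.NAVIGATIONAL
    if is_keyword_query(query, clicked_documents):
        return QueryClass.KEYWORD
    return QueryClass.NON_KEYWORD


def split_training_sets(
    click_log: Sequence[ClickRecord],
    queries: Sequence[Query] | Mapping[str, Query],
    corpus: Sequence[Document] | Mapping[str, Document],
    nav_patterns: Sequence[str] | None = None,
    nav_predicate: Callable[[str], bool] | None = None,
) -> tuple[list[ClickRecord], list[ClickRecord], dict[str, QueryClass]]:
    """Split an aggregated click log into retriever and re-ranker pairs.

    Returns (retriever_pairs, reranker_pairs, classes).  retriever_pairs are
    all pairs from informational (non-navigational) queries; reranker_pairs
    the subset whose query is NON_KEYWORD.  Pairs with unresolvable doc_ids
    are dropped with a warning.
    """
    docs = corpus if isinstance(corpus, Mapping) else {d.doc_id: d for d in corpus}
    qmap = queries if isinstance(queries, Mapping) else {q.query_id: q for q in queries}

    by_query: dict[str, list[ClickRecord]] = {}
    dropped = 0
    for rec in click_log:
        if rec.doc_id not in docs:
            dropped += 1
            continue
        by_query.setdefault(rec.query_id, []).append(rec)
    if dropped:
        logger.warning("split_training_sets: dropped %d pairs with unknown doc_id",
                       dropped)

    retriever_pairs: list[ClickRecord] = []
    reranker_pairs: list[ClickRecord] = []
    classes: dict[str, QueryClass] = {}
    counts = {c: 0 for c in QueryClass}
    for qid in sorted(by_query):
        recs = by_query[qid]
        clicked = [docs[r.doc_id] for r in recs]
        cls = classify_query(qmap[qid], clicked, nav_patterns, nav_predicate)
        classes[qid] = cls
        counts[cls] += 1
        if cls is QueryClass.NAVIGATIONAL:
            continue
        retriever_pairs.extend(recs)
        if cls is QueryClass.NON_KEYWORD:
            reranker_pairs.extend(recs)
    logger.info("split_training_sets: %d navigational, %d keyword, %d non-keyword "
                "queries; %d retriever pairs, %d reranker pairs",
                counts[QueryClass.NAVIGATIONAL], counts[QueryClass.KEYWORD],
                counts[QueryClass.NON_KEYWORD], len(retriever_pairs),
                len(reranker_pairs))
    if not reranker_pairs and retriever_pairs:
        logger.warning("split_training_sets: re-ranker training set is empty "
                       "(every informational query is a keyword query)")
    return retriever_pairs, reranker_pairs, classes
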