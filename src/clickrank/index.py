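"""Offline document encoding and exact maximum-inner-product search.

The reference implementation is a brute-force scan of a flat embedding
matrix: at desk scale nothing approximate is needed, and exactness makes
hard-negative mining reproducible.  An approximate backend can be plugged
in behind the same contract but is never used by default.

Persistence: ``matrix.npy`` (n x h float64) + ``index.json`` sidecar with
the ordered doc_ids, h and the encoder's vocab hash; reload is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import Document, RankedList
from .encoders import SequenceEncoder, build_doc_ids


@dataclass
class DenseIndex:
    doc_ids: list[str]
    matrix: np.ndarray          # (n, h), row i embeds doc_ids[i]
    meta: dict

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.doc_ids):
            raise ValueError("matrix rows must match doc_ids")

    @property
    def size(self) -> int:
        return len(self.doc_ids)

    @property
    def hidden_size(self) -> int:
        return self.matrix.shape[1]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "matrix.npy", self.matrix)
        with open(out / "index.json", "w", encoding="utf-8") as fh:
            json.dump({"doc_ids": self.doc_ids, "h": self.hidden_size,
                       **self.meta}, fh, sort_keys=True)

    @classmethod
    def load(cls, in_dir: str | Path) -> "DenseIndex":
        p = Path(in_dir)
        with open(p / "index.json", encoding="utf-8") as fh:
            side = json.load(fh)
        matrix = np.load(p / "matrix.npy")
        doc_ids = side.pop("doc_ids")
        side.pop("h", None)
        return cls(doc_ids=doc_ids, matrix=matrix, meta=side)


def build_index(corpus: Sequence[Document], doc_encoder: SequenceEncoder,
                batch_size: int = 64) -> DenseIndex:
    """Encode every document offline into a flat inner-product index."""
    if not corpus:
        raise ValueError("corpus is empty")
    seqs = [build_doc_ids(doc_encoder.tokenizer, d.title, d.abstract,
                          doc_encoder.config) for d in corpus]
    rows = [doc_encoder.encode_batch(seqs[i:i + batch_size])
            for i in range(0, len(seqs), batch_size)]
    return DenseIndex(
        doc_ids=[d.doc_id for d in corpus],
        matrix=np.concatenate(rows, axis=0),
        meta={"vocab_hash": doc_encoder.tokenizer.vocab_hash()},
    )


def search(index: DenseIndex, query_vec: np.ndarray, k: int) -> RankedList:
    """Exact top-k by inner product; ties broken by doc_id ascending."""
    return search_batch(index, np.asarray(query_vec)[None, :], k, ["_q"])[0]


def search_batch(index: DenseIndex, query_vecs: np.ndarray, k: int,
                 query_ids: Sequence[str]) -> list[RankedList]:
    q = np.asarray(query_vecs, dtype=np.float64)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if q.ndim != 2 or q.shape[1] != index.hidden_size:
        raise ValueError(f"query vectors must be (m, {index.hidden_size})")
    scores = q @ index.matrix.T                      # (m, n)
    ids = np.asarray(index.doc_ids)
    k_eff = min(k, index.size)
    out: list[RankedList] = []
    for qi, qid in enumerate(query_ids):
        s = scores[qi]
        # lexsort: primary key is the last one (-score), ties fall back to doc_id
        order = np.lexsort((ids, -s))[:k_eff]
        rl = RankedList(qid, [(str(ids[j]), float(s[j])) for j in order])
        out.append(rl)
    return out
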