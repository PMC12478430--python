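"""Encoder contracts and small trainable reference implementations.

Three roles, mirroring a bi-encoder + cross-encoder architecture:

* query tower:    vector = Enc([CLS] q [SEP]) at the CLS position
* document tower: vector = Enc([CLS] title [SEP] abstract [SEP]) at CLS
* pair scorer:    score  = W^T Enc([CLS] q [SEP] title abstract [SEP]) + b

Two interchangeable architectures are provided.  ``transformer`` is a tiny
2-layer single-head transformer encoder with learned positions and CLS
pooling — the architecture family of production biomedical encoders, at toy
size.  ``bag`` is a position-gated bag-of-embeddings encoder followed by a
2-layer MLP; it has no token-token attention but trains an order of
magnitude faster, which makes it the default for desk-scale experiments.
Both run on the package's own autodiff engine (float64, deterministic).

Constructors accept an optional external checkpoint identifier which is
stored as pass-through metadata only; no pretrained weights are required or
bundled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .autograd import Tensor
from .corpus_io import normalize_ws

PAD, CLS, SEP, UNK = 0, 1, 2, 3
_N_SPECIAL = 4


class Tokenizer:
    """Whitespace tokenizer over a fixed, sorted vocabulary.

    Lowercases, splits on Unicode whitespace, maps out-of-vocabulary tokens
    to UNK.  Special ids: PAD=0, CLS=1, SEP=2, UNK=3; regular tokens start
    at 4.
    """

    def __init__(self, vocab: Sequence[str]):
        self.vocab = sorted(set(vocab))
        self.token_to_id = {t: i + _N_SPECIAL for i, t in enumerate(self.vocab)}

    @classmethod
    def from_texts(cls, texts: Iterable[str]) -> "Tokenizer":
        tokens: set[str] = set()
        for t in texts:
            tokens.update(normalize_ws(t).lower().split())
        return cls(sorted(tokens))

    @property
    def size(self) -> int:
        return len(self.vocab) + _N_SPECIAL

    def vocab_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.vocab).encode("utf-8"))
        return h.hexdigest()[:16]

    def tokenize(self, text: str) -> list[int]:
        return [self.token_to_id.get(t, UNK)
                for t in normalize_ws(text).lower().split()]


@dataclass(frozen=True)
class EncoderConfig:
    arch: str = "bag"                  # "bag" | "transformer"
    hidden_size: int = 64
    n_layers: int = 2
    max_query_len: int = 64            # token budget per segment, excl. specials
    max_doc_len: int = 256
    max_joint_len: int = 320
    init_scale: float = 0.1
    seed: int = 0
    checkpoint: str | None = None      # external checkpoint id, pass-through

    def __post_init__(self):
        if self.arch not in ("bag", "transformer"):
            raise ValueError(f"unknown encoder arch {self.arch!r}")


# ------------------------------------------------------------ input templates

def build_query_ids(tok: Tokenizer, text: str, cfg: EncoderConfig) -> list[int]:
    ids = tok.tokenize(text)[: cfg.max_query_len]
    if not ids:
        raise ValueError(f"query {text!r} is empty after tokenization/truncation")
    return [CLS] + ids + [SEP]


def build_doc_ids(tok: Tokenizer, title: str, abstract: str,
                  cfg: EncoderConfig) -> list[int]:
    t_ids = tok.tokenize(title)[: cfg.max_doc_len]
    a_ids = tok.tokenize(abstract)[: max(cfg.max_doc_len - len(t_ids), 0)]
    if not t_ids:
        raise ValueError("document title is empty after tokenization/truncation")
    return [CLS] + t_ids + [SEP] + a_ids + [SEP]


def build_joint_ids(tok: Tokenizer, query: str, title: str, abstract: str,
                    cfg: EncoderConfig) -> list[int]:
    q_ids = tok.tokenize(query)[: cfg.max_query_len]
    if not q_ids:
        raise ValueError(f"query {query!r} is empty after tokenization/truncation")
    d_budget = max(cfg.max_joint_len - len(q_ids), 1)
    d_ids = (tok.tokenize(title) + tok.tokenize(abstract))[:d_budget]
    return [CLS] + q_ids + [SEP] + d_ids + [SEP]


def _pad_batch(seqs: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    idx = np.full((len(seqs), T), PAD, dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=np.float64)
    for i, s in enumerate(seqs):
        idx[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return idx, mask


# ------------------------------------------------------------------- encoders

class SequenceEncoder:
    """Base: maps padded token-id batches to (B, h) CLS representations."""

    def __init__(self, config: EncoderConfig, tokenizer: Tokenizer,
                 seed_offset: int = 0):
        self.config = config
        self.tokenizer = tokenizer
        self.max_pos = max(config.max_doc_len, config.max_joint_len,
                           config.max_query_len) + 8
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed + seed_offset))
        for p in self.params.values():
            p.requires_grad = True

    def _init_params(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def forward(self, seqs: Sequence[Sequence[int]]) -> Tensor:
        raise NotImplementedError

    def encode_batch(self, seqs: Sequence[Sequence[int]]) -> np.ndarray:
        return self.forward(seqs).data.copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def param_count(self) -> int:
        return sum(p.data.size for p in self.params.values())


class BagEncoder(SequenceEncoder):
    """Position-gated bag-of-embeddings + 2-layer MLP, CLS-inclusive pooling.

    pooled = mean_t emb[id_t] * (1 + pos_t);  out = tanh(pooled W1 + b1) W2 + b2
    The multiplicative position gate makes the output order-sensitive.
    """

    def _init_params(self, rng) -> None:
        h, s = self.config.hidden_size, self.config.init_scale
        V = self.tokenizer.size
        self.params = {
            "emb": Tensor(rng.normal(0.0, s, (V, h))),
            "pos": Tensor(rng.normal(0.0, s, (self.max_pos, h))),
            "W1": Tensor(rng.normal(0.0, 1.0 / np.sqrt(h), (h, h))),
            "b1": Tensor(np.zeros(h)),
            "W2": Tensor(rng.normal(0.0, 1.0 / np.sqrt(h), (h, h))),
            "b2": Tensor(np.zeros(h)),
        }

    def forward(self, seqs):
        idx, mask = _pad_batch(seqs)
        P = self.params
        emb = P["emb"].take(idx)                              # (B,T,h)
        pos = P["pos"].take(np.arange(idx.shape[1])[None, :])  # (1,T,h)
        x = emb * (pos + 1.0) * Tensor(mask[:, :, None])
        lengths = mask.sum(axis=1, keepdims=True)             # (B,1)
        pooled = x.sum(axis=1) / Tensor(lengths)
        h1 = (pooled @ P["W1"] + P["b1"]).tanh()
        return h1 @ P["W2"] + P["b2"]


class TransformerEncoder(SequenceEncoder):
    """2-layer (configurable) single-head transformer encoder, post-layernorm,
    learned absolute positions, CLS pooling."""

    _LN_EPS = 1e-5

    def _init_params(self, rng) -> None:
        h, s = self.config.hidden_size, self.config.init_scale
        V = self.tokenizer.size
        w = 1.0 / np.sqrt(h)
        P = {
            "emb": Tensor(rng.normal(0.0, s, (V, h))),
            "pos": Tensor(rng.normal(0.0, s, (self.max_pos, h))),
        }
        for l in range(self.config.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                P[f"l{l}.{name}"] = Tensor(rng.normal(0.0, w, (h, h)))
            P[f"l{l}.F1"] = Tensor(rng.normal(0.0, w, (h, 4 * h)))
            P[f"l{l}.f1"] = Tensor(np.zeros(4 * h))
            P[f"l{l}.F2"] = Tensor(rng.normal(0.0, 1.0 / np.sqrt(4 * h), (4 * h, h)))
            P[f"l{l}.f2"] = Tensor(np.zeros(h))
            for ln in ("ln1", "ln2"):
                P[f"l{l}.{ln}.g"] = Tensor(np.ones(h))
                P[f"l{l}.{ln}.b"] = Tensor(np.zeros(h))
        self.params = P

    def _layernorm(self, x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return (xc / ((var + self._LN_EPS) ** 0.5)) * g + b

    def forward(self, seqs):
        idx, mask = _pad_batch(seqs)
        P = self.params
        h = self.config.hidden_size
        x = P["emb"].take(idx) + P["pos"].take(np.arange(idx.shape[1])[None, :])
        key_bias = Tensor(((1.0 - mask) * -1e9)[:, None, :])  # (B,1,T)
        for l in range(self.config.n_layers):
            q = x @ P[f"l{l}.Wq"]
            k = x @ P[f"l{l}.Wk"]
            v = x @ P[f"l{l}.Wv"]
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(h)) + key_bias
            attn = scores.softmax(axis=-1)
            x = self._layernorm(x + (attn @ v) @ P[f"l{l}.Wo"],
                                P[f"l{l}.ln1.g"], P[f"l{l}.ln1.b"])
            f = ((x @ P[f"l{l}.F1"] + P[f"l{l}.f1"]).relu()
                 @ P[f"l{l}.F2"] + P[f"l{l}.f2"])
            x = self._layernorm(x + f, P[f"l{l}.ln2.g"], P[f"l{l}.ln2.b"])
        return x[:, 0, :]


def make_encoder(config: EncoderConfig, tokenizer: Tokenizer,
                 seed_offset: int = 0) -> SequenceEncoder:
    cls = BagEncoder if config.arch == "bag" else TransformerEncoder
    return cls(config, tokenizer, seed_offset)


def make_bi_encoder(config: EncoderConfig, tokenizer: Tokenizer,
                    share_embeddings: bool = False
                    ) -> tuple[SequenceEncoder, SequenceEncoder]:
    """Build the two retriever towers (unshared parameters by default).

    With ``share_embeddings`` the towers remain distinct networks but share
    one token/position embedding table — a desk-scale stand-in for the
    shared pretrained initialization that full-scale bi-encoders start
    from: a query token unseen in training queries still carries the
    semantics it acquired from document occurrences.  Off by default to
    keep the two towers fully separate.
    """
    q_enc = make_encoder(config, tokenizer, seed_offset=0)
    d_enc = make_encoder(config, tokenizer, seed_offset=1)
    if share_embeddings:
        for k in ("emb", "pos"):
            d_enc.params[k] = q_enc.params[k]
    return q_enc, d_enc


def warm_start_embeddings(target: "SequenceEncoder | CrossEncoderScorer",
                          source: SequenceEncoder) -> None:
    """Copy the source's token/position embeddings into target (shapes must
    match).  Used to initialize the cross-encoder from the trained
    retriever, mirroring how full-scale rerankers start from the same
    pretrained model as the retriever rather than from scratch."""
    tgt = target.encoder if isinstance(target, CrossEncoderScorer) else target
    for k in ("emb", "pos"):
        if tgt.params[k].data.shape != source.params[k].data.shape:
            raise ValueError(f"embedding shape mismatch for {k!r}")
        tgt.params[k].data = source.params[k].data.copy()


def init_reranker_from_retriever(scorer: "CrossEncoderScorer",
                                 doc_encoder: SequenceEncoder) -> None:
    """Initialize a cross-encoder from the trained retriever's document tower.

    Without any pretrained language model, a from-scratch cross-encoder has
    no token semantics to build its query-document interaction on and tends
    to spend its capacity memorizing training pairs.  This initializer is
    the desk-scale analog of starting the re-ranker from the same pretrained
    model as the retriever:

    * token/position embeddings are copied from the document tower, their
      rows norm-equalized (topical direction is kept, frequency-driven
      magnitude is discarded), and frozen;
    * for the transformer architecture, attention projections start at the
      identity so that initial attention follows embedding similarity and
      training refines it rather than discovering it from scratch.

    The interaction layers and the scoring head remain fully trainable.
    """
    warm_start_embeddings(scorer, doc_encoder)
    enc = scorer.encoder
    E = enc.params["emb"].data
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    enc.params["emb"].data = E / np.maximum(norms, 1e-8) * norms.mean()
    for k in ("emb", "pos"):
        enc.params[k].requires_grad = False
    if isinstance(enc, TransformerEncoder):
        h = enc.config.hidden_size
        for l in range(enc.config.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                enc.params[f"l{l}.{name}"].data = np.eye(h)


class CrossEncoderScorer:
    """Cross-encoder relevance: score = W^T Enc([CLS] q [SEP] d [SEP])_CLS + b."""

    def __init__(self, config: EncoderConfig, tokenizer: Tokenizer,
                 seed_offset: int = 0):
        self.encoder = make_encoder(config, tokenizer, seed_offset)
        self.config = config
        self.tokenizer = tokenizer
        rng = np.random.default_rng(config.seed + seed_offset + 104729)
        h = config.hidden_size
        self.W = Tensor(rng.normal(0.0, 1.0 / np.sqrt(h), (h,)), requires_grad=True)
        self.b = Tensor(np.zeros(()), requires_grad=True)

    @property
    def params(self) -> dict[str, Tensor]:
        return {**self.encoder.params, "head.W": self.W, "head.b": self.b}

    def forward(self, seqs: Sequence[Sequence[int]]) -> Tensor:
        reps = self.encoder.forward(seqs)                     # (B,h)
        return reps @ self.W.reshape((self.config.hidden_size, 1)) + self.b

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ----------------------------------------------------------------- public API

def encode_query(encoder: SequenceEncoder, text: str) -> np.ndarray:
    return encode_queries(encoder, [text])[0]


def encode_queries(encoder: SequenceEncoder, texts: Sequence[str]) -> np.ndarray:
    seqs = [build_query_ids(encoder.tokenizer, t, encoder.config) for t in texts]
    return encoder.encode_batch(seqs)


def encode_document(encoder: SequenceEncoder, title: str,
                    abstract: str = "") -> np.ndarray:
    return encode_documents(encoder, [(title, abstract)])[0]


def encode_documents(encoder: SequenceEncoder,
                     docs: Sequence[tuple[str, str]]) -> np.ndarray:
    seqs = [build_doc_ids(encoder.tokenizer, t, a, encoder.config)
            for t, a in docs]
    return encoder.encode_batch(seqs)


def score_pair(scorer: CrossEncoderScorer, query: str, title: str,
               abstract: str = "") -> float:
    return float(score_pairs(scorer, [(query, title, abstract)])[0])


def score_pairs(scorer: CrossEncoderScorer,
                triples: Sequence[tuple[str, str, str]]) -> np.ndarray:
    seqs = [build_joint_ids(scorer.tokenizer, q, t, a, scorer.config)
            for q, t, a in triples]
    return scorer.forward(seqs).data.reshape(-1).copy()


# ---------------------------------------------------------------- checkpoints

def _flatten(params: dict[str, Tensor]) -> tuple[np.ndarray, list[tuple[str, list[int]]]]:
    order = sorted(params)
    shapes = [(k, list(params[k].data.shape)) for k in order]
    flat = np.concatenate([params[k].data.reshape(-1) for k in order])
    return flat, shapes


def _unflatten(flat: np.ndarray, shapes: list[tuple[str, list[int]]],
               params: dict[str, Tensor]) -> None:
    off = 0
    for k, shape in shapes:
        n = int(np.prod(shape)) if shape else 1
        params[k].data = flat[off:off + n].reshape(shape)
        off += n


def save_checkpoint(obj: SequenceEncoder | CrossEncoderScorer,
                    out_dir: str | Path) -> None:
    """Self-describing checkpoint: meta.json (config, vocab, param manifest,
    vocab hash) + params.npy (flat float64, sorted key order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = obj.params
    flat, shapes = _flatten(params)
    kind = "scorer" if isinstance(obj, CrossEncoderScorer) else "encoder"
    tok = obj.tokenizer
    meta = {
        "kind": kind,
        "config": asdict(obj.config),
        "param_shapes": shapes,
        "vocab": tok.vocab,
        "vocab_hash": tok.vocab_hash(),
    }
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, sort_keys=True)
    np.save(out / "params.npy", flat)


def load_checkpoint(ckpt_dir: str | Path) -> SequenceEncoder | CrossEncoderScorer:
    ckpt = Path(ckpt_dir)
    with open(ckpt / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    cfg = EncoderConfig(**meta["config"])
    tok = Tokenizer(meta["vocab"])
    if tok.vocab_hash() != meta["vocab_hash"]:
        raise ValueError(f"vocab hash mismatch in checkpoint {ckpt}")
    obj: SequenceEncoder | CrossEncoderScorer
    if meta["kind"] == "scorer":
        obj = CrossEncoderScorer(cfg, tok)
    else:
        obj = make_encoder(cfg, tok)
    flat = np.load(ckpt / "params.npy")
    _unflatten(flat, [(k, s) for k, s in meta["param_shapes"]], obj.params)
    return obj
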