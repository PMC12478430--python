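# Methods

This note records what the package computes, the modelling and numerical
choices behind it, and what the desk-scale experiments do and do not show.

## Training objectives

The retriever loss is the click-weighted bidirectional in-batch softmax
cross-entropy described in the README. Two points are deliberate:

* **Raw inner products.** The softmax is taken over unnormalized
  `E(q)ᵀE(d)`; there is no temperature and no L2 normalization, and the
  same raw inner product drives index search, so training and inference
  score identically.
* **Direction mixing.** The two directional batch losses are combined as
  `λ·L^q2d + (1−λ)·L^d2q` with λ = 0.5 by default; λ is a config knob
  (`loss_mix`) because equal weighting is a convention, not a constraint.
  Click weights are applied *within* each direction before mixing.

Both losses are computed with log-sum-exp stabilization; a batch of one
instance has loss exactly 0 (softmax over a single candidate), and
non-finite embeddings or scores raise instead of propagating NaNs.

In-batch duplicate documents are treated as negatives, matching the loss
equations literally; `mask_duplicates=True` masks colliding rows/columns
out of the softmax for users whose logs contain heavy duplication (off by
default).

The re-ranker instance loss is the NLL of the clicked document among the
`M+1` cross-encoder scores. Batch losses reuse the `log2(c+1)`-normalized
click weights of the positives (`unweighted` switches to a plain mean):
click counts carry the only graded relevance signal a click log has, and
using the same weighting in both stages keeps them consistent.

## Encoders

Two interchangeable architectures implement the same contract (token-id
sequence → R^h at the CLS position), both on the package's own float64
reverse-mode autodiff engine:

* `transformer` — 2 layers, single head, learned absolute positions,
  post-layernorm, GELU-free (ReLU) feed-forward, CLS pooling. This is the
  architecture-faithful reference and the default for the cross-encoder,
  whose job — query-document interaction — is exactly what cross-attention
  computes.
* `bag` — a position-gated bag of embeddings (`mean_t emb_t · (1+pos_t)`)
  followed by a 2-layer MLP. It keeps order sensitivity through the
  position gate but has no token-token interaction. It is the default for
  the retriever towers: it trains an order of magnitude faster in numpy
  and the bi-encoder objective (pooled-embedding inner products) suits it.

Truncation budgets default to 64 query / 256 document / 320 joint tokens
and are config keys. Templates are `[CLS] q [SEP]`,
`[CLS] title [SEP] abstract [SEP]` and `[CLS] q [SEP] title abstract
[SEP]`; truncation never removes special tokens. The two towers are
independent networks by default; `share_embeddings=True` ties their
token/position tables (see below). Constructors accept an external
checkpoint identifier as pass-through metadata only.

Default training configurations (Adam, constant LR): retriever batch 32,
2000 steps, lr 1e-2; re-ranker batch 16, 600 steps, lr 1e-3. The large
retriever step size is a consequence of training *from scratch*: these are
not pretrained towers being fine-tuned (where ~1e-4 is customary) but
randomly initialized tiny encoders that must build their embedding table
within the step budget.

## Cross-encoder initialization

A from-scratch cross-encoder cannot be trained usefully from a few hundred
mined instances: its embedding table (the bulk of its parameters) lets it
memorize pair identities faster than it can discover the generalizable
query-document interaction, and measured topic discrimination on held-out
queries stays at noise level for any learning rate or step count. Full
scale systems sidestep this by initializing retriever and re-ranker from
the same pretrained language model. The desk-scale analog implemented in
`init_reranker_from_retriever` (and `train-reranker --init-from`):

1. copy token/position embeddings from the *trained document tower*;
2. norm-equalize the embedding rows (keep topical direction, discard
   frequency-driven magnitude);
3. freeze the embeddings — this removes the memorization sink and forces
   the trainable interaction layers to use generalizable features;
4. initialize the transformer's attention projections to the identity, so
   initial attention follows embedding similarity and training refines an
   informative structure rather than searching for one.

With this recipe the trained two-stage system matches or exceeds
retriever-only NDCG@10 on held-out queries for every tested seed; without
any one of steps 1–3 it reliably falls below it.

## Synthetic worlds

`generate_world` emulates the statistical structure click-log training
assumes. Topics have disjoint 40-token core vocabularies plus a shared
background pool; documents draw 70% of their tokens from their topic core;
each query targets one topic. Clicked documents (5 per query) get qrels
grade 2 and click counts `1 + Poisson(click_scale · 2)` (clicks are
thereby always ≥ 1); all other same-topic documents get grade 1. A
`keyword_fraction` of queries is constructed to satisfy the keyword rule —
half as single tokens, half as two-token phrases injected verbatim into
every clicked abstract — and the planted class of every query is recorded
for exact recovery checks. `click_noise_rate` adds a single spurious
cross-topic click per affected query (such noise can legitimately flip a
planted phrase-keyword label, which is why recovery checks run at noise
0). Tokens are fixed-width pseudo-words (`w00042`) so substring matching
in the keyword filter behaves like token matching.

Defaults: 20 topics × 100 documents × 10 queries, vocabulary 5000, noise
0.05, `keyword_fraction` 0.5. Real PubMed-style logs are far more
keyword-heavy (~90%), but at 200 queries that ratio would leave too few
non-keyword queries to exercise re-ranker training; 0.5 keeps both
training sets populated. What the generator does **not** model: position
bias in clicks, query reformulation/sessions, realistic vocabulary
overlap between topics, and document length variation. Passing tests on
these worlds therefore demonstrate that the training machinery extracts
planted topical signal under click weighting and hard-negative mining —
not that the defaults would reproduce production-scale retrieval quality.

## Desk-scale behaviour worth knowing

* **Generalization is query-token-bound.** Held-out queries use topic-core
  tokens that may never occur in *training queries*; with unshared towers
  those tokens' query-side embeddings stay near their random
  initialization, which caps held-out NDCG@10 around 0.32–0.40 while
  training-query NDCG@10 exceeds 0.95. Tying the towers' embedding tables
  (`share_embeddings=True`) lets query tokens inherit document-side
  semantics and raises held-out NDCG@10 to ≈ 0.5 on the default world; it
  is off by default to keep the two-tower architecture pure.
* **The mining window overlaps true relevance at this scale.** With 100
  relevant documents per topic, ranks 31–100 of a well-trained retriever
  contain many same-topic (unclicked, hence "negative") documents. About a
  third of mined negatives are cross-topic — that contrast is what the
  re-ranker actually learns from; the same-topic portion is irreducible
  label noise, since clicked subsets are random among same-topic articles.

## Numerical and procedural choices

* Everything is float64; gradient checks against central differences hold
  to 1e-4 relative.
* All rankings order by score descending with ties broken by doc_id
  ascending; combined with seeded shuffling/sampling this makes every
  stage byte-reproducible, which the test suite asserts on checkpoints,
  indexes, mined instances and run files.
* MIPS is an exact brute-force scan of a flat float64 matrix; approximate
  backends can implement the same contract but are excluded from
  correctness guarantees.
* NDCG uses linear gain by default (exponential `2^r − 1` is an option);
  MAP binarizes at grade ≥ 1 and divides by `min(R, k)`. Queries without a
  positively graded document are excluded from means and logged.
* Embedding-task similarity defaults to the inner product (consistent with
  the training objective); cosine is switchable.
* The "exact mention" in the keyword rule is a case-insensitive contiguous
  substring of title + " " + abstract after whitespace normalization —
  the strictest simple reading; the one-word test splits on Unicode
  whitespace only, so hyphenated terms count as one word.
* Navigational filtering ships as a transparent regex stub (author-style
  and bracketed-field-tag patterns) with a predicate hook, because the
  production classifier for this step is external to the method.
* Mining uses the frozen trained retriever once; there is no iterative
  re-mining during re-ranker training.
* `holdout_split` is stratified by topic and deterministic given its seed;
  experiment scripts hold out 20% of queries.

## Problem sizes used by the test and acceptance runs

Unit tests run on a 3-topic × 12-document × 6-query world with h=16
encoders. The end-to-end experiments (test suite and
`scripts/acceptance.py`) use the default 20 × 100 × 10 world with h=64
encoders, 2000 retriever steps, mining window e=31..f=100 with M=7, 600
re-ranker steps, first-stage K=100 and final k=10, averaged over three
seeds — sizes chosen so a full cycle stays within minutes per seed on one
CPU.

## Known limitations

* The tiny encoders have no subword tokenizer; out-of-vocabulary tokens
  map to UNK, so transfer to natural text requires plugging in a real
  tokenizer and encoder behind the same contracts.
* The re-ranker's gain over the retriever at desk scale is small
  (≈ +0.01 NDCG@10 held-out) because its only learnable signal is topic
  matching; with richer worlds (graded within-topic structure) the margin
  would widen.
* Click counts enter only through `log2(c+1)` weights; no position-bias
  correction is applied.
* `holdout_split` requires ≥ 2 queries per topic and the generator
  requires disjoint topic cores — degenerate configurations fail fast
  with explicit errors rather than degrading silently.
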