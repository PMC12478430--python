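"""Local-negative mining and cross-encoder training."""

import math

import numpy as np
import pytest

import clickrank as cr
from clickrank.index import DenseIndex
from clickrank.reranker import RerankerInstance, nll_from_scores


def brute_force_nll(scores):
    """Independent reference: softmax cross-entropy over the M+1 scores."""
    s = np.asarray(scores, float)
    e = np.exp(s - s.max())
    return -math.log(e[0] / e.sum())


class TestInstanceLoss:
    def test_lone_positive_is_zero(self):
        assert nll_from_scores([2.5]) == 0.0

    def test_uniform_scores_give_log_m_plus_one(self):
        assert nll_from_scores([0.7, 0.7, 0.7, 0.7]) == pytest.approx(
            math.log(4), abs=1e-12)

    def test_hand_value(self):
        # s+=2, two negatives at 0: -ln(e^2 / (e^2 + 2))
        expected = -math.log(math.e ** 2 / (math.e ** 2 + 2))
        assert nll_from_scores([2.0, 0.0, 0.0]) == pytest.approx(expected,
                                                                 abs=1e-9)
        assert expected == pytest.approx(0.2395, abs=1e-4)

    @pytest.mark.parametrize("m", [0, 1, 7])
    def test_matches_brute_force(self, m):
        rng = np.random.default_rng(m)
        s = rng.normal(scale=3, size=m + 1)
        assert nll_from_scores(s) == pytest.approx(brute_force_nll(s), abs=1e-6)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            nll_from_scores([np.nan, 0.0])

    def test_positive_never_among_negatives(self):
        with pytest.raises(ValueError):
            RerankerInstance("q", "text", "d1", ("d2", "d1"), 1)


class TestMining:
    @pytest.fixture()
    def ranked_index(self):
        """10 docs whose retriever ranking is d01 > d02 > ... > d10."""
        n = 10
        ids = [f"d{i:02d}" for i in range(1, n + 1)]
        matrix = np.array([[float(n - i)] for i in range(n)])
        return DenseIndex(doc_ids=ids, matrix=matrix, meta={})

    @pytest.fixture()
    def one_dim_query_encoder(self):
        class Stub:
            config = cr.EncoderConfig(hidden_size=1)

            def encode(self, texts):
                return np.ones((len(texts), 1))
        return Stub()

    def _mine(self, pairs, index, cfg):
        # encode_queries is bypassed with a stub: mine against constant query
        # vectors so ranks follow the index construction above
        queries = {p.query_id: cr.Query(p.query_id, "x y z") for p in pairs}

        class QEnc:
            tokenizer = None
            config = cr.EncoderConfig(hidden_size=1)

            def forward(self, seqs):
                raise NotImplementedError

            def encode_batch(self, seqs):  # pragma: no cover
                raise NotImplementedError

        import clickrank.reranker as rr_mod
        original = rr_mod.encode_queries
        rr_mod.encode_queries = lambda enc, texts: np.ones((len(texts), 1))
        try:
            return cr.mine_local_negatives(pairs, queries, index, QEnc(), cfg)
        finally:
            rr_mod.encode_queries = original

    def test_window_pool_equal_to_m_takes_all(self, ranked_index):
        pairs = [cr.ClickRecord("q1", "d01", 2)]
        out = self._mine(pairs, ranked_index,
                         cr.MiningConfig(e=4, f=8, m=5, seed=0))
        assert out[0].neg_doc_ids == ("d04", "d05", "d06", "d07", "d08")

    def test_clicked_doc_inside_window_is_excluded(self, ranked_index):
        pairs = [cr.ClickRecord("q1", "d05", 2)]
        out = self._mine(pairs, ranked_index,
                         cr.MiningConfig(e=4, f=8, m=4, seed=0))
        assert out[0].neg_doc_ids == ("d04", "d06", "d07", "d08")

    def test_insufficient_pool_drops_instance(self, ranked_index):
        pairs = [cr.ClickRecord("q1", "d05", 2)]
        out = self._mine(pairs, ranked_index,
                         cr.MiningConfig(e=4, f=8, m=5, seed=0))
        assert out == []

    def test_f_clamped_to_index_size(self, ranked_index):
        pairs = [cr.ClickRecord("q1", "d01", 2)]
        out = self._mine(pairs, ranked_index,
                         cr.MiningConfig(e=4, f=99, m=5, seed=0))
        assert set(out[0].neg_doc_ids) <= {f"d{i:02d}" for i in range(4, 11)}

    def test_same_seed_is_deterministic(self, ranked_index):
        pairs = [cr.ClickRecord("q1", "d01", 2), cr.ClickRecord("q2", "d02", 1)]
        cfg = cr.MiningConfig(e=2, f=9, m=3, seed=42)
        assert self._mine(pairs, ranked_index, cfg) == \
               self._mine(pairs, ranked_index, cfg)

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            cr.MiningConfig(e=5, f=3)


def test_mined_negatives_lie_in_window_and_avoid_clicks(tiny_world,
                                                        tiny_tokenizer):
    """Real-encoder mining: every negative's retriever rank is within [e, f]
    and never a clicked document of its query."""
    cfg = cr.EncoderConfig(arch="bag", hidden_size=16, seed=0)
    q_enc, d_enc = cr.make_bi_encoder(cfg, tiny_tokenizer)
    idx = cr.build_index(tiny_world.corpus, d_enc)
    pairs, _, _ = cr.split_training_sets(tiny_world.click_log,
                                         tiny_world.queries, tiny_world.corpus)
    mcfg = cr.MiningConfig(e=5, f=20, m=3, seed=1)
    instances = cr.mine_local_negatives(pairs, tiny_world.queries, idx, q_enc,
                                        mcfg)
    assert instances
    clicked = {}
    for p in pairs:
        clicked.setdefault(p.query_id, set()).add(p.doc_id)
    qmap = {q.query_id: q for q in tiny_world.queries}
    for inst in instances:
        qvec = cr.encode_query(q_enc, qmap[inst.query_id].text)
        ranked = cr.search(idx, qvec, mcfg.f).doc_ids()
        for neg in inst.neg_doc_ids:
            rank = ranked.index(neg) + 1
            assert mcfg.e <= rank <= mcfg.f
            assert neg not in clicked[inst.query_id]


class TestTraining:
    @pytest.fixture()
    def instances(self, tiny_world, tiny_tokenizer):
        cfg = cr.EncoderConfig(arch="bag", hidden_size=16, seed=0)
        q_enc, d_enc = cr.make_bi_encoder(cfg, tiny_tokenizer)
        idx = cr.build_index(tiny_world.corpus, d_enc)
        pairs, _, _ = cr.split_training_sets(
            tiny_world.click_log, tiny_world.queries, tiny_world.corpus)
        return cr.mine_local_negatives(pairs, tiny_world.queries, idx, q_enc,
                                       cr.MiningConfig(e=5, f=20, m=3, seed=1))

    def _scorer(self, tiny_tokenizer, seed=0):
        return cr.CrossEncoderScorer(
            cr.EncoderConfig(arch="bag", hidden_size=16, seed=seed),
            tiny_tokenizer)

    def test_uniform_clicks_make_batch_loss_the_mean(self, tiny_world,
                                                     tiny_tokenizer, instances):
        uniform = [RerankerInstance(i.query_id, i.query_text, i.pos_doc_id,
                                    i.neg_doc_ids, clicks=3)
                   for i in instances[:4]]
        scorer = self._scorer(tiny_tokenizer)
        docs = {d.doc_id: d for d in tiny_world.corpus}
        res = cr.train_reranker(
            uniform, scorer, tiny_world.corpus,
            cr.TrainConfig(batch_size=4, steps=1, learning_rate=0.0, seed=0))
        fresh = self._scorer(tiny_tokenizer)
        expected = np.mean([cr.reranker_instance_loss(fresh, i, docs)
                            for i in uniform])
        assert res.loss_trace[0] == pytest.approx(expected, abs=1e-9)

    def test_same_seed_gives_identical_traces(self, tiny_world, tiny_tokenizer,
                                              instances):
        traces = []
        for _ in range(2):
            scorer = self._scorer(tiny_tokenizer)
            res = cr.train_reranker(
                instances, scorer, tiny_world.corpus,
                cr.TrainConfig(batch_size=4, steps=15, learning_rate=1e-3,
                               seed=9))
            traces.append(res.loss_trace)
        assert traces[0] == traces[1]

    def test_loss_decreases(self, tiny_world, tiny_tokenizer, instances):
        scorer = self._scorer(tiny_tokenizer)
        res = cr.train_reranker(
            instances, scorer, tiny_world.corpus,
            cr.TrainConfig(batch_size=4, steps=150, learning_rate=1e-2, seed=0))
        assert np.mean(res.loss_trace[-10:]) < np.mean(res.loss_trace[:10])

    def test_empty_instances_rejected(self, tiny_world, tiny_tokenizer):
        with pytest.raises(ValueError):
            cr.train_reranker([], self._scorer(tiny_tokenizer),
                              tiny_world.corpus, cr.TrainConfig(steps=1))


def test_instance_io_round_trip(tmp_path):
    instances = [RerankerInstance("q1", "some text", "d1", ("d2", "d3"), 4),
                 RerankerInstance("q2", "other text", "d9", (), 1)]
    cr.write_instances(instances, tmp_path / "inst.jsonl")
    assert cr.read_instances(tmp_path / "inst.jsonl") == instances
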