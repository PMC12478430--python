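"""Shared fixtures: a small synthetic world and encoders sized for speed."""

from __future__ import annotations

import pytest

import clickrank as cr


TINY_SPEC = cr.WorldSpec(
    n_topics=3, vocab_size=400, docs_per_topic=12, queries_per_topic=6,
    keyword_fraction=0.5, click_noise_rate=0.0, click_scale=2.0, seed=7,
)


@pytest.fixture(scope="session")
def tiny_world() -> cr.World:
    return cr.generate_world(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_tokenizer(tiny_world) -> cr.Tokenizer:
    return cr.build_tokenizer(tiny_world.corpus, tiny_world.queries)


@pytest.fixture()
def small_encoder_config() -> cr.EncoderConfig:
    return cr.EncoderConfig(arch="bag", hidden_size=16, seed=0,
                            max_query_len=16, max_doc_len=48, max_joint_len=64)


@pytest.fixture()
def docs3() -> list[cr.Document]:
    return [
        cr.Document("d1", "breast cancer screening guidelines",
                    "screening for breast cancer in adults"),
        cr.Document("d2", "cholesterol lowering drugs",
                    "statins reduce ldl cholesterol"),
        cr.Document("d3", "breast cancer screening trial",
                    "a randomized breast cancer screening trial"),
    ]
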