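"""Shared fixtures: one mid-size synthetic corpus, its pipeline output, fixtures."""
from __future__ import annotations

import pytest

from forumvigil import ingest as ing
from forumvigil import synthetic as syn
from forumvigil import terminology as tm

CORPUS_SEED = 42


@pytest.fixture(scope="session")
def terminology() -> tm.Terminology:
    return syn.default_terminology()


@pytest.fixture(scope="session")
def corpus_config() -> syn.CorpusConfig:
    """10,000 posts across 8 quarters with every planted artifact active."""
    return syn.CorpusConfig(
        fora=["inspire", "breastcancer", "healthunlocked", "melanoma"],
        n_authors=400,
        n_posts=10_000,
        period=("2015Q1", "2016Q4"),
        ae_injection=[
            syn.InjectionSchedule(drug="denosumab", pt_code="PT0001",
                                  kind="ramp", p_start=0.10, p_end=0.30),
            syn.InjectionSchedule(drug="denosumab", pt_code="PT0005",
                                  kind="constant", p_start=0.08),
            syn.InjectionSchedule(drug="pembrolizumab", pt_code="PT0007",
                                  kind="step", p_start=0.02, p_end=0.10,
                                  step_quarter="2016Q1"),
        ],
        dup_rate=0.08,
        spam_rate=0.05,
        pii_rate=0.10,
        relevance_rate=0.85,
        seed=CORPUS_SEED,
    )


@pytest.fixture(scope="session")
def corpus(corpus_config):
    return syn.generate_corpus(corpus_config)


@pytest.fixture(scope="session")
def pipeline(corpus, corpus_config):
    posts, _ = corpus
    return ing.run_pipeline(
        posts,
        syn.DEFAULT_SPAM_LEXICON,
        corpus_config.drug_lexicons,
        syn.DEFAULT_NAME_DICTIONARY,
    )


@pytest.fixture(scope="session")
def matched_events(pipeline, terminology):
    return [e for p in pipeline.posts for e in tm.match_events(p, terminology)]
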