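import pytest

from pvsignal.curation import (build_corpus, code_events, load_toy_meddra,
                               primary_suspect_caseids)
from pvsignal.synth import SynthConfig, generate_quarter

TARGET = "CHOLESTYRAMINE"
PLANTED_PT = "Constipation"


def planted_config(n_cases=5000, seed=0, rr=5.0, **kw):
    return SynthConfig(
        n_cases=n_cases, seed=seed,
        rr_matrix={TARGET: {PLANTED_PT: rr}}, **kw)


def make_coded_corpus(config):
    """Generator -> dedup -> toy-MedDRA coding, returning corpus + bundle."""
    bundle = generate_quarter(config)
    corpus, _ = build_corpus(bundle)
    corpus, _ = code_events(corpus, load_toy_meddra())
    return corpus, bundle


@pytest.fixture(scope="session")
def toy_map():
    return load_toy_meddra()


@pytest.fixture(scope="session")
def small_planted():
    """A modest planted-signal corpus shared across read-only tests."""
    config = planted_config(n_cases=5000, seed=3)
    corpus, bundle = make_coded_corpus(config)
    target = primary_suspect_caseids(corpus, [TARGET])
    return {"config": config, "bundle": bundle, "corpus": corpus,
            "target": target}
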