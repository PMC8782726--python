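import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoscreen.config import ScreeningConfig
from mitoscreen.fixtures import (FixtureSpec, make_pretraining_corpus,
                                 make_reference_panel, make_screening_library)
from mitoscreen.representations import Mol2vecEncoder
from mitoscreen.scoring import VirtualScreen

settings.register_profile("default", derandomize=True, deadline=None,
                          suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def panel(default_spec):
    return make_reference_panel(default_spec)


@pytest.fixture(scope="session")
def library_and_labels(default_spec, panel):
    records, labels = make_screening_library(default_spec, panel)
    return records, {l["compound_id"]: l["class"] for l in labels}


# --- small, fast objects for unit tests -------------------------------------

@pytest.fixture(scope="session")
def small_corpus():
    return make_pretraining_corpus(FixtureSpec(n_corpus=150))


@pytest.fixture(scope="session")
def small_encoder(small_corpus):
    return Mol2vecEncoder(vector_size=32, window=5, epochs=2, seed=7).fit(small_corpus)


# --- the full default-condition screen, shared across end-to-end tests ------

@pytest.fixture(scope="session")
def default_encoder(default_spec):
    corpus = make_pretraining_corpus(default_spec)
    return Mol2vecEncoder(seed=0).fit(corpus)


@pytest.fixture(scope="session")
def default_screen(default_encoder, panel, library_and_labels):
    """Fitted screen + full ranking of the default synthetic library."""
    records, labels = library_and_labels
    cfg = ScreeningConfig(seed=0)
    vs = VirtualScreen(encoder=default_encoder, config=cfg).fit(panel)
    ranking = vs.score_library(records)
    return vs, ranking, labels
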