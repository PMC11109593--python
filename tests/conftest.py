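import dataclasses

import pytest

from trialmine.schema import default_schema_path, load_entity_schema
from trialmine.simulate import default_signal_config, generate_corpus


@pytest.fixture(scope="session")
def schema():
    return load_entity_schema(default_schema_path())


@pytest.fixture(scope="session")
def schema_by_id(schema):
    return {s.entity_id: s for s in schema}


@pytest.fixture(scope="session")
def small_corpus():
    """20 clean synthetic studies (near-window arm mentions, no synonyms)."""
    return generate_corpus(default_signal_config(seed=11, n_docs=20))


@pytest.fixture(scope="session")
def synonym_corpus():
    cfg = dataclasses.replace(
        default_signal_config(seed=12, n_docs=20), synonym_noise=True
    )
    return generate_corpus(cfg)
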