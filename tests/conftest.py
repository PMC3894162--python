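import pytest
from hypothesis import settings

from phytomine.corpus_synthesis import CorpusConfig, generate_corpus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from phytomine.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition fixture bundle shared across tests."""
    return generate_corpus(CorpusConfig(), seed=7)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()
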