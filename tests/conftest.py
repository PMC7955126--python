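import numpy as np
import pytest

from apafind import pipeline
from apafind.model import ModelConfig
from apafind.synthetic import SimConfig, generate


@pytest.fixture(scope="session")
def small_fixture():
    """24-transcript fixture for fast structural tests."""
    return generate(SimConfig(n_transcripts=24, seed=5))


@pytest.fixture(scope="session")
def small_sequences(small_fixture):
    fx = small_fixture
    return pipeline.build_sequences(
        fx.transcripts, fx.genome, fx.coverage, truth=fx.sites, merge=True
    )


@pytest.fixture(scope="session")
def easy_fixture():
    """The easy study-condition fixture: 200 transcripts, strong signals."""
    return generate(SimConfig(n_transcripts=200, seed=1))


@pytest.fixture(scope="session")
def easy_trained(easy_fixture):
    """Model trained on the easy fixture plus its test-split report."""
    fx = easy_fixture
    model, report = pipeline.fit(
        fx.transcripts, fx.genome, fx.coverage, fx.sites,
        model_config=ModelConfig(seed=1),
    )
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
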