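import pytest

from trial_access.synth import SynthConfig, generate_all


@pytest.fixture(scope="session")
def cfg():
    """A small but complete synthetic study population configuration."""
    return SynthConfig(seed=11, n_areas=200, n_facilities=12, n_patients=4000)


@pytest.fixture(scope="session")
def tables(cfg):
    """All generated tables plus planted ground truth for the session config."""
    return generate_all(cfg)
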