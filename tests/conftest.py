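import numpy as np
import pytest

from iurhythm import SynthConfig, generate_envelope


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def default_synth():
    """One default-configuration synthetic conversation (300 s, 4 speakers)."""
    env, ann = generate_envelope(SynthConfig(), seed=1)
    return env, ann


@pytest.fixture(scope="session")
def short_synth():
    """A short synthetic conversation for cheap end-to-end tests."""
    env, ann = generate_envelope(SynthConfig(duration_s=60.0, n_speakers=2),
                                 seed=3)
    return env, ann
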