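import numpy as np
import pytest

from lfpdecode.preprocess import preprocess_session
from lfpdecode.synth import CouplingSpec, NoiseSpec, SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """30 s default session used by cheap unit tests."""
    return generate_session(SynthConfig(duration=30.0, seed=1))


@pytest.fixture(scope="session")
def small_features(small_session):
    return preprocess_session(small_session)


def strong_coupling_config(seed: int, duration: float = 180.0) -> SynthConfig:
    """Strong, uniformly coupled fixture: m = 0.8 on every channel and band."""
    return SynthConfig(
        duration=duration,
        seed=seed,
        coupling=CouplingSpec(depth=np.full((8, 6), 0.8)),
        noise=NoiseSpec(white_sd=0.3, pink_amplitude=0.3),
    )


@pytest.fixture(scope="session")
def strong_features():
    """Preprocessed 3-minute strong-coupling session (decoding fixture)."""
    session = generate_session(strong_coupling_config(seed=0))
    return preprocess_session(session)
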