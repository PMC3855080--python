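import numpy as np
import pytest

from syldiscrim import build_continuum, synthesize


@pytest.fixture(scope="session")
def continua():
    """The three study continua, built once."""
    return {name: build_continuum(name) for name in ("ba_da", "ba_wa", "ga_ka")}


@pytest.fixture(scope="session")
def endpoint_waveforms(continua):
    """Synthesized reference and far-endpoint syllables of each continuum."""
    out = {}
    for name, cont in continua.items():
        out[name] = {
            "first": synthesize(cont.syllables[0], seed=11),
            "last": synthesize(cont.syllables[-1], seed=11),
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
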