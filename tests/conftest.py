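import numpy as np
import pytest

from oleochem import (GeneratorConfig, SampleMeta, Spectrum, SpectrumSet,
                      build_endmember_library)


@pytest.fixture(scope="session")
def library():
    return build_endmember_library()


@pytest.fixture(scope="session")
def gen_cfg():
    """Default generator settings with a fixed test seed."""
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def grid(gen_cfg):
    return gen_cfg.grid()


def make_spectrum(wn, ab, sample_id="s1", oil_type="CAO", **meta_kwargs):
    return Spectrum(np.asarray(wn, float), np.asarray(ab, float),
                    SampleMeta(sample_id=sample_id, oil_type=oil_type, **meta_kwargs))


@pytest.fixture
def toy_spectrum():
    """Small descending-grid spectrum used for container round-trips."""
    wn = np.arange(1800.0, 648.0, -2.0)
    ab = 0.1 + 0.05 * np.cos(wn / 70.0)
    return make_spectrum(wn, ab)
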