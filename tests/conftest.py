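import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compounds():
    from halonet.dereplication import load_compounds

    return load_compounds()


@pytest.fixture(scope="session")
def neutral_losses():
    from halonet.dereplication import load_neutral_losses

    return load_neutral_losses()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, n_peaks, precursor, id="s"):
    """A random spectrum helper shared by networking tests."""
    from halonet.spectra import Spectrum

    mz = np.sort(rng.uniform(100.0, precursor - 20.0, n_peaks))
    intensity = rng.uniform(10.0, 1000.0, n_peaks)
    return Spectrum(id, precursor, 1.0, mz, intensity)
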