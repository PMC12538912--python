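import pytest

from asdscreen import felodipine_hpmc, fit_chi_temperature_model


@pytest.fixture
def mixture():
    """Felodipine / Affinisol HPMC reference pair with m = 100."""
    return felodipine_hpmc()


@pytest.fixture
def reference_model():
    """chi(T) = A + B/T through the published felodipine-HPMC anchors:
    chi = 4.11 at 298 K (Hansen route) and 0.441 at the drug's melting
    point, 415.25 K (depression route)."""
    return fit_chi_temperature_model([(298.0, 4.11), (415.25, 0.441)])
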