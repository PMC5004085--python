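import pytest
from hypothesis import settings

settings.register_profile("famscape", derandomize=True, deadline=None)
settings.load_profile("famscape")

from famscape.gridspace import GridSpec, VARIED_FRACTIONS, records_to_frame
from famscape.ode_engine import load_surrogate_config
from famscape.synthetic_data import load_fixtures, make_synthetic_db

TOY_LEVELS = (0.5, 1.0, 1.5)
TOY_ELEAK = (-60.0, -55.0)


@pytest.fixture(scope="session")
def toy_spec():
    """3 fraction levels per conductance, 2 E_leak levels: 4,374 points."""
    return GridSpec(**{p: TOY_LEVELS for p in VARIED_FRACTIONS},
                    e_leak_levels=TOY_ELEAK)


@pytest.fixture(scope="session")
def toy_db(toy_spec):
    return make_synthetic_db(toy_spec, seed=1)


@pytest.fixture(scope="session")
def toy_frame(toy_db):
    return records_to_frame(toy_db)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def surrogate():
    return load_surrogate_config()
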