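import numpy as np
import pytest

import divegas as dv


@pytest.fixture(scope="session")
def green_config() -> dv.TurtleConfig:
    """Control green turtle (70 kg), the main workhorse configuration."""
    return dv.make_config("green", 70.0)


@pytest.fixture(scope="session")
def leatherback_config() -> dv.TurtleConfig:
    return dv.make_config("leatherback", 350.0)


@pytest.fixture()
def square_dive_series():
    """10 s surface, 20 min at 50 m, 2 min surface."""
    return dv.DepthSeries(np.concatenate(
        [np.zeros(10), np.full(1200, 50.0), np.zeros(120)]))


@pytest.fixture(scope="session")
def mixed_bout_series():
    """Seeded three-bin leatherback bout (60 dives) shared across tests."""
    spec = dv.BoutSpec(
        species=dv.Species.LEATHERBACK, body_mass=350.0, n_dives=60, seed=7,
        bins={
            "shallow": dv.BinSpec(33.3, 209, 251, 6.3, 7.0),
            "medium": dv.BinSpec(33.3, 827, 157, 49.1, 14.4),
            "deep": dv.BinSpec(33.4, 839, 97, 108.7, 15.3),
        })
    return dv.generate_bout(spec)
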