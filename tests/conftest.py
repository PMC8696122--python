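import pytest

from lncnet.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 2 tissues x 3 stages x 3 reps, NB noise."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Deterministic limit: perfect planted correlations, no count noise."""
    return simulate(
        SimulationConfig(
            seed=7,
            corr_strength=1.0,
            nb_dispersion=0.0,
            library_cv=0.0,
            decoy_rate=0.0,
        )
    )
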