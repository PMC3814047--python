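import pytest

from erp import SynthParams, generate_universe, worked_example_fig2, worked_example_section3


@pytest.fixture(scope="session")
def fig2_universe():
    """Fixture realizing the printed two-domain worked example."""
    return worked_example_fig2()


@pytest.fixture(scope="session")
def section3_universe():
    """Two single-entry scenarios: exact match, subset match, failure."""
    return worked_example_section3()


@pytest.fixture(scope="session")
def random_universe():
    """A small noisy universe with cross-pool architectures for oracle tests."""
    params = SynthParams(
        n_domains=20,
        n_entries=60,
        n_ecs=8,
        pool_size=10,
        co_occurrence_strength=0.7,
        signal_mode="noisy",
        noise_rate=0.08,
        seed=11,
    )
    universe, _truth = generate_universe(params)
    return universe
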