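import pytest

from barleymut.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def dataset():
    """Default-scale synthetic study (2 Mb genome, 11 lines, 13 landraces)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def big_dataset():
    """Larger draw counts for parameter-recovery checks (>=5,000 induced
    SNVs and indels, 50,000 landrace segregating sites)."""
    cfg = SimulationConfig(
        seed=7,
        mean_induced_snv=1000.0,
        mean_induced_indel=500.0,
        n_landrace_segsites=50_000,
    )
    return simulate(cfg)
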