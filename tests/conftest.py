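import pytest

from tescan import synthetic_data as sd


@pytest.fixture(scope="session")
def default_world():
    """The standard study-condition world: 6 classes, one carrying a
    4-site tandem Myb array and 7-fold ChIP enrichment, depth 1e5."""
    return sd.generate_world(sd.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_chip_reads(default_world):
    return default_world.reads("chip")


@pytest.fixture(scope="session")
def default_input_reads(default_world):
    return default_world.reads("input")


@pytest.fixture(scope="session")
def small_world():
    """A tiny divergence-free world for exact-placement oracles."""
    cfg = sd.SimulationConfig(
        n_classes=3,
        instances_per_class=4,
        per_copy_divergence=0.0,
        flank_length=2000,
        n_genes=3,
        depth=3000,
        seed=7,
    )
    return sd.generate_world(cfg)
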