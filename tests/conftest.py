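import pytest

import alphacomp.simulate as sim


@pytest.fixture(scope="session")
def zero_rate_config() -> sim.SimulationConfig:
    """All evolutionary rates off: every genome identical to the root."""
    return sim.SimulationConfig(
        n_taxa=6,
        root_gene_count=40,
        protein_length_mean=80.0,
        protein_length_sd=15.0,
        gain_rate=0.0,
        loss_rate=0.0,
        dup_rate=0.0,
        inversion_rate=0.0,
        translocation_rate=0.0,
        subst_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_rate_dataset(zero_rate_config):
    return sim.simulate_dataset(zero_rate_config)


@pytest.fixture(scope="session")
def rogue_preset():
    return sim.rogue_lineage_preset(1)


@pytest.fixture(scope="session")
def rogue_dataset(rogue_preset):
    return sim.simulate_dataset(rogue_preset.config)
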