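import pytest

import spvae


@pytest.fixture(scope="session")
def small_bundle():
    """A small but structured grouped simulation shared across tests."""
    config = spvae.SimulationConfig(
        n_cells_per_group=200,
        n_shared_genes=120,
        n_program_genes=40,
        n_cell_types=3,
        n_programs_per_group=2,
        seed=7,
    )
    return spvae.simulate_grouped_counts(config)
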