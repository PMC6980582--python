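import pandas as pd
import pytest

from tegenomics.simulate import SimulationConfig, simulate_all


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast default configuration for test simulations."""
    params = dict(
        seed=seed,
        n_scaffolds=2,
        scaffold_length=200_000,
        n_genes=60,
        gene_length=900,
        frac_te_surrounded=0.25,
        n_families=5,
        copies_per_family=5,
        family_length=400,
        n_secreted=12,
        n_ssp=8,
        n_excluded_decoys=4,
        n_cazyme=10,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(small_config())


@pytest.fixture()
def fpkm_table():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "hyphae": [0.0, 10.0, 1.0, 5.0],
            "primordia": [2.5, 0.5, 1.0, 5.0],
            "fruiting_body": [0.0, 0.5, 1.0, 0.1],
        }
    )
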