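import numpy as np
import pandas as pd
import pytest

from epimarks import SimulationConfig, simulate_cohort
from epimarks.differential import PairwiseDesign


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny two-species cohort with zero measurement noise."""
    cfg = SimulationConfig(
        n_genes=60,
        n_species=2,
        seed=11,
        noise_sd_marks=np.zeros(5),
        noise_sd_expr=0.0,
        emulate_missing_individual=False,
    )
    sample_table, gene_table, truth = simulate_cohort(cfg)
    return cfg, sample_table, gene_table, truth


@pytest.fixture
def toy_design():
    """Balanced 8+8 two-species design with alternating sexes."""
    ids = [f"A{i}" for i in range(1, 9)] + [f"B{i}" for i in range(1, 9)]
    return PairwiseDesign(
        species_a="A",
        species_b="B",
        individual_ids=ids,
        species=np.array(["A"] * 8 + ["B"] * 8),
        sex=np.array((["M", "F"] * 4) * 2),
    )


@pytest.fixture
def null_matrix(toy_design):
    rng = np.random.default_rng(5)
    genes = [f"g{i:03d}" for i in range(40)]
    return pd.DataFrame(
        rng.normal(size=(40, 16)), index=genes, columns=toy_design.individual_ids
    )
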