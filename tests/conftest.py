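import numpy as np
import pytest

from svarda.experiments import default_run_config
from svarda.pipeline import run_pipeline
from svarda.synthetic_data import (
    LineageTree,
    SimulationConfig,
    generate_genome,
    simulate_lineage_insertions,
    synthesize_rda_reads,
)


def small_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A reduced synthetic study for fast unit tests."""
    params = dict(
        seed=seed,
        chrom_sizes={"chr1": 300_000, "chr2": 200_000, "chr3": 150_000},
        te_counts={"SINE": 120, "LINE": 60, "LTR": 20, "DNA": 15, "Satellite": 5},
        n_germline_sva=8,
        n_genes=10,
        branch_counts={
            ("Cereb",): 20,
            ("Bulb",): 20,
            ("Hippo",): 20,
            ("Pfc",): 20,
            ("Calca",): 20,
            ("Calca", "Pfc"): 10,
            ("Calca", "Hippo", "Pfc"): 10,
            ("Bulb", "Calca", "Hippo", "Pfc"): 10,
            ("Bulb", "Calca", "Cereb", "Hippo", "Pfc"): 5,
        },
        n_donors=1,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(small_sim_config())


@pytest.fixture(scope="session")
def small_truth_and_reads(small_genome):
    cfg = small_sim_config()
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_lineage_insertions(small_genome, LineageTree(), cfg, "D1", rng)
    reads = synthesize_rda_reads(truth, small_genome, cfg, rng)
    return cfg, truth, reads


@pytest.fixture(scope="session")
def default_run():
    """The full default synthetic study (5 regions x 2 donors, 2,000
    insertions/donor, 1% artifacts, 1% leak-through, exact alignment)."""
    return run_pipeline(default_run_config(seed=1))
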