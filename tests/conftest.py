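import numpy as np
import pytest

from creglink.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort shared by unit tests (fast to generate)."""
    cfg = SimulationConfig(
        n_samples=2,
        n_cancer_types=2,
        cells_per_sample=300,
        n_peaks=600,
        n_genes=220,
        n_motifs=20,
        matches_per_motif=15,
        n_planted_links=10,
        n_planted_programs=2,
        program_gene_count=30,
        n_planted_dars=15,
        n_tumor_tfs=3,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
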