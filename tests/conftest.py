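import pytest

from nanotcr import SimulationConfig, simulate_repertoire


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-cell cohort with realistic noise (multi-chain cells,
    nonproductive contigs, ambient pMHC background)."""
    return simulate_repertoire(SimulationConfig(n_cells=300, n_clonotypes=30, seed=7))


@pytest.fixture(scope="session")
def clean_dataset():
    """A noiseless cohort: every contig productive, no ambient pMHC counts,
    dominant fraction exactly 1 — for exact-recovery checks."""
    cfg = SimulationConfig(n_cells=200, n_clonotypes=20, seed=7,
                           productive_rate=1.0, ambient_noise=0.0,
                           dominant_fraction_beta=0.0)
    return simulate_repertoire(cfg)
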