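import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    from haplopass.simulate import simulate_panel

    return simulate_panel(
        n_breeds=3,
        haps_per_breed=6,
        n_sites=300,
        chrom_length_bp=3_000_000,
        founder_div=0.2,
        mutation_rate=0.01,
        recomb_switch_rate=5e-7,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    from haplopass.simulate import simulate_cohort

    return simulate_cohort(
        small_panel,
        n_individuals=12,
        n_cases=3,
        mosaic_switch_rate=1e-7,
        private_allele_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
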