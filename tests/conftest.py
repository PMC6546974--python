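import numpy as np
import pytest

from mima.immunoediting import build_gene_rates
from mima.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-case cohort reused by recovery tests."""
    config = CohortConfig(
        n_cases=2,
        metastases_per_case=(5, 8),
        stem_mutations_mean=60,
        clade_mutations_mean=30,
        private_mutations_mean=15,
        tcr_clones_per_site=40,
        cells_per_sample=150,
        n_genes=150,
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_rates(small_cohort):
    return build_gene_rates(small_cohort.reference_catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
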