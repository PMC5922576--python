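import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


@pytest.fixture
def small_cohort_config():
    """Small, fast cohort for structural tests (not the study conditions)."""
    from ngsadequacy.synthetic import CohortConfig

    return CohortConfig(
        seed=11,
        n_specimens=300,
        n_genes=5,
        bases_per_gene=8,
        n_mrna_genes=6,
        n_cn_genes=6,
        n_rules=12,
        base_mean_associations=8.0,
        tumor_bin_association_means=(3.0, 6.0, 7.0, 7.5, 8.0),
        area_bin_association_means=(1.5, 5.0, 6.5, 7.5, 8.0),
    )
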