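import numpy as np
import pytest

from gradeweaver.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort with consistent plants, reused across read-only tests."""
    cfg = CohortConfig(
        n_g1=30, n_g2=20, n_g3=30, n_genes=400, n_mirnas=60,
        n_informative_up=20, n_informative_down=20, delta=1.5, noise_sd=1.0, seed=3,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
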