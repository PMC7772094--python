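import numpy as np
import pytest

from sca1vol import SimConfig, simulate_atlas_stack, simulate_cohort, simulate_sara


@pytest.fixture(scope="session")
def cohort_default():
    """Paper-scale cohort (13 affected / 20 unaffected) with SARA, dropout on."""
    cfg = SimConfig(seed=11)
    cohort, params = simulate_cohort(cfg)
    return simulate_sara(cohort, params, cfg), params


@pytest.fixture(scope="session")
def cohort_full():
    """99-row cohort: same design with the third visit fully retained."""
    cfg = SimConfig(seed=12, dropout_prob_affected=0.0,
                    third_visit_cap_unaffected=None)
    cohort, params = simulate_cohort(cfg)
    return simulate_sara(cohort, params, cfg), params


@pytest.fixture(scope="session")
def atlas_ladder():
    """Small atlas stack whose Jacobian correlations form a known ladder."""
    return simulate_atlas_stack((16, 16, 16), n_candidates=5, n_label_sets=3,
                                seed=5,
                                jacobian_correlations=[0.9, 0.7, 0.5, 0.3, 0.1])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
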