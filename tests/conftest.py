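import pytest

from gmnet.cohort import measures_from_loadings
from gmnet.ica import fit_ica
from gmnet.synth import SynthConfig, make_ground_truth, simulate_cohort

# small conditions for unit tests: 4 networks over 40 regions
SMALL_CFG = SynthConfig(n_regions=40, k_networks=4, support_min=3, support_max=8)


@pytest.fixture(scope="session")
def gt_small():
    return make_ground_truth(SMALL_CFG, seed=101)


@pytest.fixture(scope="session")
def cohort_small(gt_small):
    """20 subjects per phenotype x arm cell: 120 subjects, 480 visits."""
    return simulate_cohort(gt_small, n_subjects=20, seed=102)


@pytest.fixture(scope="session")
def ica_small(cohort_small):
    return fit_ica(cohort_small[0], K=4, seed=103, max_iter=500)


@pytest.fixture(scope="session")
def measures_small(cohort_small, ica_small):
    return measures_from_loadings(cohort_small[0], ica_small.loadings)


# default study conditions: 8 networks over 60 regions, 600 subjects
@pytest.fixture(scope="session")
def gt_default():
    return make_ground_truth(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def cohort_default(gt_default):
    return simulate_cohort(gt_default, n_subjects=100, seed=12)


@pytest.fixture(scope="session")
def ica_default(cohort_default):
    return fit_ica(cohort_default[0], K=8, seed=13, max_iter=500)


@pytest.fixture(scope="session")
def measures_default(cohort_default, ica_default):
    return measures_from_loadings(cohort_default[0], ica_default.loadings)
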