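import warnings

import pytest

from organclock.kdm import fit_kdm_all, score_dataset
from organclock.lifestyle import build_hli_records, categorize_change
from organclock.synthetic import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")
warnings.filterwarnings("ignore", message="overflow encountered")


@pytest.fixture(scope="session")
def study_cohort():
    """Small study-condition cohort shared by the slower integration tests."""
    return generate_cohort(CohortConfig(n_individuals=1500, seed=11))


@pytest.fixture(scope="session")
def study_scored(study_cohort):
    data, truth = study_cohort
    hli = build_hli_records(data)
    changes = categorize_change(hli)
    params = fit_kdm_all(data)
    ba = score_dataset(data, params)
    return data, truth, hli, changes, params, ba
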