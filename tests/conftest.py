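import pytest

from g6pdhb import calibrate_default_config, simulate_cohort
from g6pdhb.pipeline import prepare_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort under default (calibrated) conditions."""
    return simulate_cohort(calibrate_default_config(n=4000, seed=11))


@pytest.fixture(scope="session")
def prepared_default_cohort(default_cohort):
    """The same cohort after haplotype calling, status resolution,
    classification and exclusions."""
    return prepare_cohort(default_cohort)
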