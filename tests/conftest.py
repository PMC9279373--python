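import pytest

from fastlabel.fasting_labeler import LabelerConfig, label_cohort
from fastlabel.glucose_conditioning import condition
from fastlabel.synthetic_emr import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A noisy 800-patient cohort shared across tests (read-only)."""
    return generate_cohort(GeneratorConfig(n_patients=800, seed=11))


@pytest.fixture(scope="session")
def conditioned(small_cohort):
    retained, ledger = condition(small_cohort.glucose)
    return retained, ledger


@pytest.fixture(scope="session")
def labeled(small_cohort, conditioned):
    retained, _ = conditioned
    lab, sd_ref = label_cohort(
        retained, small_cohort.hba1c, small_cohort.patients, LabelerConfig()
    )
    return lab, sd_ref
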