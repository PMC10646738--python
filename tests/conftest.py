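import pytest

from bloodaudit import BloodOrderAudit, reference_records
from bloodaudit.synthetic import REFERENCE_RECOMMENDATION_FLOORS


@pytest.fixture(scope="session")
def reference_cohort():
    """All reference-audit procedure cohorts as exact records."""
    return reference_records()


@pytest.fixture(scope="session")
def reference_results(reference_cohort):
    """Fitted audit of the reference cohort with its clinical recommendation floors."""
    return BloodOrderAudit(reference_cohort).fit(overrides=REFERENCE_RECOMMENDATION_FLOORS)
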