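import pytest

from thyverify.cohort import TestResult, apply_exclusions, flow_counts
from thyverify.performance import AdjustmentConfig, adjust_counts, tally_verified
from thyverify.replica import study_replica_cohort

# the molecular-test result enum starts with "Test"; keep pytest from
# trying to collect it as a test class in modules that import it
TestResult.__test__ = False


@pytest.fixture(scope="session")
def replica():
    """The full 256-record study-replica cohort (exclusions still flagged)."""
    return study_replica_cohort()


@pytest.fixture(scope="session")
def analysis_cohort(replica):
    cohort, _ = apply_exclusions(replica)
    return cohort


@pytest.fixture(scope="session")
def replica_flow(analysis_cohort):
    return flow_counts(analysis_cohort)


@pytest.fixture(scope="session")
def replica_verified(analysis_cohort):
    return tally_verified(analysis_cohort)


@pytest.fixture(scope="session")
def replica_adjusted(replica_verified):
    return adjust_counts(replica_verified, AdjustmentConfig())
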