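import pandas as pd
import pytest
from hypothesis import settings

import amyloid_cutpoint as ac

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_bundle() -> ac.CohortBundle:
    """Reconstructed 78-subject validation cohort (20 printed + 58 padded)."""
    return ac.load_error_table_fixture()


@pytest.fixture(scope="session")
def composite_cutoffs() -> pd.DataFrame:
    """Published composite cutoffs as a cutoff table."""
    return pd.DataFrame(
        [
            {"target_region": "composite", "reference_region": rr, "cutoff": c}
            for rr, c in ac.COMPOSITE_CUTOFFS.items()
        ]
    )


@pytest.fixture(scope="session")
def fixture_validation(fixture_bundle, composite_cutoffs) -> dict:
    """Full validation run of the published cutoffs on the fixture cohort."""
    va = fixture_bundle.subjects[["subject_id", "va_status"]].rename(
        columns={"va_status": "status"}
    )
    return ac.run_validate(
        fixture_bundle.suvr,
        composite_cutoffs,
        pathology_status=fixture_bundle.pathology,
        va=va,
    )
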