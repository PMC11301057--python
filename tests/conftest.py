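import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import aers_signal as a
from aers_signal import synthetic_faers as sf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: The target-drug search terms used throughout the tests.
TERMS = sf.TARGET_DRUG_TERMS


@pytest.fixture(scope="session")
def fixture_db() -> sf.SyntheticFaers:
    return sf.small_fixture()


@pytest.fixture(scope="session")
def fixture_deduped(fixture_db):
    return a.deduplicate(a.assemble_case_reports(fixture_db.tables))


@pytest.fixture(scope="session")
def fixture_cohort(fixture_deduped):
    cohort, background = a.extract_cohort(
        fixture_deduped, a.CohortSpec(drug_terms=TERMS)
    )
    return cohort, background


@pytest.fixture(scope="session")
def fixture_events(fixture_deduped, fixture_db) -> pd.DataFrame:
    return a.code_events(fixture_deduped, fixture_db.pt_soc_map)


def fixture_run_config(out_dir) -> "a.RunConfig":
    """The exact run configuration frozen into the golden bundle."""
    return a.RunConfig(
        input_dir="unused",
        output_dir=str(out_dir),
        pt_soc_map="unused",
        drug_terms=TERMS,
        subgroup_min_cohort=2,
        subgroup_top_k=5,
    )
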