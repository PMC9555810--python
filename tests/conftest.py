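import pytest
from hypothesis import settings

import kanodemand as kd

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixtures():
    return kd.load_study_fixtures()


@pytest.fixture(scope="session")
def study_dataset(fixtures):
    """Respondent-level dataset rebuilt from the packaged per-attribute counts."""
    return kd.reconstruct_from_counts(
        list(fixtures.attribute_counts.values()), catalogue=fixtures.catalogue
    )


@pytest.fixture(scope="session")
def study_metrics(study_dataset):
    return kd.analyze_survey(study_dataset)


@pytest.fixture(scope="session")
def evaluation_table():
    return kd.build_evaluation_table()
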