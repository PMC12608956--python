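import pandas as pd
import pytest

from patsteps import clean_dataset, preset_study_like, run_analysis, simulate_dataset


@pytest.fixture(scope="session")
def study_df() -> pd.DataFrame:
    """Study-like synthetic trial table (14 participants, 4 PATs)."""
    return simulate_dataset(preset_study_like(seed=7))


@pytest.fixture(scope="session")
def study_data(study_df):
    return clean_dataset(study_df)


@pytest.fixture(scope="session")
def study_report(study_df):
    return run_analysis(study_df)
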