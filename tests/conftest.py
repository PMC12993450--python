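import numpy as np
import pandas as pd
import pytest

from ventricsf.cohort import default_params, simulate_cohort
from ventricsf.phantom import ParticipantRecord, simulate_phantom


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The calibrated 378-participant cohort at a fixed seed."""
    return simulate_cohort(default_params(), seed=11)


@pytest.fixture(scope="session")
def sample_records(default_cohort):
    """A spread of participant records across stages and volumes."""
    idx = np.linspace(0, len(default_cohort) - 1, 8).astype(int)
    return [ParticipantRecord.from_row(default_cohort.iloc[i]) for i in idx]


@pytest.fixture(scope="session")
def sample_bundle(sample_records):
    """One mid-cohort phantom with PET volumes."""
    return simulate_phantom(sample_records[4], seed=42)
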