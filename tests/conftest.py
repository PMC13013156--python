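import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stroopnorm as sn

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def healthy_df() -> pd.DataFrame:
    """Default synthetic healthy normative cohort (n = 452), as a frame."""
    cohort = sn.generate_cohort(sn.healthy_cohort_spec(seed=11))
    return sn.cohort_to_frame(cohort)


@pytest.fixture(scope="session")
def published_norms():
    return sn.load_published_norms()


@pytest.fixture(scope="session")
def published_grids():
    return sn.load_published_grids()


@pytest.fixture(scope="session")
def published_bands():
    return sn.load_published_bands()


@pytest.fixture(scope="session")
def clinical_adjusted(healthy_df):
    """Adjusted scores for healthy + AD + MCI groups under published norms."""
    ad = sn.cohort_to_frame(sn.simulate_patient_group(124, "AD", seed=21))
    mci = sn.cohort_to_frame(sn.simulate_patient_group(139, "MCI", seed=22))
    corr = sn.DemographicCorrector().fit()
    return {name: corr.transform(df)
            for name, df in (("healthy", healthy_df), ("AD", ad), ("MCI", mci))}
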