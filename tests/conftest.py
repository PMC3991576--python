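import numpy as np
import pandas as pd
import pytest

from hrvscreen import featurize, simulate_cohort
from hrvscreen.feature_pipeline import combine_table


@pytest.fixture(scope="session")
def cohort_features() -> pd.DataFrame:
    """Feature table of the default separable synthetic cohort (17 CHF, 30
    healthy 5-min records), with the combined features appended."""
    records, labels = simulate_cohort(seed=11)
    rows = [
        {"record_id": rr.source_id, "label": int(lab), **featurize(rr).as_dict()}
        for rr, lab in zip(records, labels)
    ]
    return combine_table(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
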