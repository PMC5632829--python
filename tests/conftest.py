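import numpy as np
import pandas as pd
import pytest

from camexposure.synthetic import GeneratorConfig, default_intensity_table, simulate_cohort
from camexposure.vocab import load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def intensity_table(vocab):
    return default_intensity_table(vocab)


@pytest.fixture(scope="session")
def small_cohort(intensity_table):
    """A compact but complete synthetic study (18 schools, 72 children, 2 days)."""
    cfg = GeneratorConfig(
        seed=77,
        include_marketing_free=False,
        intensity_table=intensity_table,
        schools_per_stratum=2,
        children_per_school=4,
        wear_days=2,
    )
    return simulate_cohort(cfg)


def coded_rows(child, times, code, base="2014-07-17T08:00:00"):
    """Build a coded-image table from offsets in seconds and one code triple."""
    setting, medium, product = code
    t0 = pd.Timestamp(base)
    return pd.DataFrame(
        {
            "child_id": child,
            "timestamp": [t0 + pd.Timedelta(seconds=s) for s in times],
            "setting": setting,
            "medium": medium,
            "product": product,
        }
    )


@pytest.fixture
def make_stream():
    return coded_rows
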