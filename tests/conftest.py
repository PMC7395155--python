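import numpy as np
import pandas as pd
import pytest

from whaledens import datasets
from whaledens.availability import summaries_from_table
from whaledens.foi_scoring import FOIRecord, classify, score_foi


@pytest.fixture(scope="session")
def reference_tags():
    """The 21 bundled per-deployment daylight surface/dive totals."""
    return summaries_from_table(datasets.tag_summaries())


@pytest.fixture(scope="session")
def reference_counts():
    return datasets.foi_counts()


@pytest.fixture(scope="session")
def reference_config():
    return datasets.survey_config()


@pytest.fixture(scope="session")
def reference_ship():
    return datasets.ship_summary()


def make_foi_record(foi_id, psi, sea_state="good", stratum="calmer", observer="O1"):
    c_s = score_foi(psi)
    return FOIRecord(
        foi_id=foi_id,
        psi=tuple(psi),
        c_s=c_s,
        label=classify(c_s),
        sea_state=sea_state,
        stratum=stratum,
        observer=observer,
    )


@pytest.fixture
def foi_record_factory():
    return make_foi_record


def random_foi_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A valid random FOI table in the CSV schema."""
    sea_states = ["ideal", "good", "average", "sub-average", "poor"]
    stratum_of = {
        "ideal": "calmer", "good": "calmer", "average": "calmer",
        "sub-average": "rougher", "poor": "rougher",
    }
    states = rng.choice(sea_states, n)
    return pd.DataFrame(
        {
            "foi_id": [f"F{i:04d}" for i in range(n)],
            **{f"psi{j}": rng.integers(0, 3, n) for j in range(1, 14)},
            "sea_state": states,
            "stratum": [stratum_of[s] for s in states],
            "observer": "O1",
        }
    )
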