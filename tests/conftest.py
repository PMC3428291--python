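import numpy as np
import pandas as pd
import pytest

from drmkit.cohort import CohortConfig, generate_study
from drmkit.core import RATING_ITEMS


def make_episode_row(
    respondent_id="R1",
    wave="test",
    set_="A",
    period="morning",
    start_min=480,
    end_min=540,
    activities="eating",
    companions="alone",
    **ratings,
):
    """One episode row with all-calm ratings unless overridden."""
    base = {item: 1 for item in RATING_ITEMS}
    base.update(calm_relaxed=2, enjoyment=2)
    base.update(ratings)
    return {
        "respondent_id": respondent_id,
        "wave": wave,
        "set": set_,
        "period": period,
        "start_min": start_min,
        "end_min": end_min,
        "activities": activities,
        "companions": companions,
        **base,
    }


def episodes_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_sim():
    """One study at the design's scale, shared across read-only tests."""
    return generate_study(CohortConfig(n_respondents=1560, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20120827)
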