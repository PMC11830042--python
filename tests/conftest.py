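import numpy as np
import pandas as pd
import pytest

from implfx.simulate import ITSSimParams, SurveySimParams, simulate_its, simulate_survey


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def step_series():
    """Noiseless level shift 10 -> 20 at month 13 (24 months)."""
    p = ITSSimParams(
        n_pre=12, n_post=12, pre_intercept=10.0, post_intercept=20.0,
        pre_sd=0.0, post_sd=0.0, seed=0,
    )
    return simulate_its(p)


@pytest.fixture(scope="session")
def small_survey():
    """3 domains x 2 components x 2 items x 40 participants (fast fits)."""
    return simulate_survey(SurveySimParams(
        n_domains=3, n_components_per_domain=2, n_items_per_component=2,
        n_participants=40, seed=7,
    ))


@pytest.fixture()
def crisp_qca_frame():
    m = pd.DataFrame(
        {"A": [1, 1, 0, 0, 1], "B": [1, 0, 1, 0, 0]},
        index=pd.Index([f"c{i}" for i in range(5)], name="case"),
        dtype=float,
    )
    y = pd.Series([1, 1, 0, 0, 1], index=m.index, dtype=float, name="outcome")
    return m, y
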