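import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from holctract.synthetic import make_scenarios
from holctract.types import TractGeometry


@pytest.fixture(scope="session")
def confounded_df() -> pd.DataFrame:
    """One draw of the confounded C-vs-B scenario (true effect 1.0)."""
    return make_scenarios(n=4000)["confounded"].generate(seed=101)


@pytest.fixture(scope="session")
def table1_df() -> pd.DataFrame:
    """One four-grade draw patterned on the study-area descriptives."""
    return make_scenarios(n=4000)["table1-like"].generate(seed=202)


@pytest.fixture()
def unit_tract() -> TractGeometry:
    return TractGeometry(tract_id="t1", geometry=box(0, 0, 1, 1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
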