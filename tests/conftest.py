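import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mcda_hh import DecisionMatrix, PanelSpec

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def two_by_seven() -> DecisionMatrix:
    """A small two-alternative, seven-criterion decision matrix with
    distinct positive entries (the study's shape)."""
    rng = np.random.default_rng(2024)
    df = pd.DataFrame(
        rng.uniform(1.0, 5.0, size=(2, 7)),
        index=["soap", "abas"],
        columns=[f"c{j}" for j in range(1, 8)],
    )
    return DecisionMatrix(df)


@pytest.fixture
def study_spec() -> PanelSpec:
    """Default simulated panel in the motivating study's shape."""
    return PanelSpec(seed=42)
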