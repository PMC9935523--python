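import pandas as pd
import pytest

import soilrisk as sr


@pytest.fixture(scope="session")
def fixture_survey() -> pd.DataFrame:
    """The built-in deterministic three-town survey (142 samples)."""
    return sr.fixture_towns()


@pytest.fixture(scope="session")
def town_means() -> pd.DataFrame:
    """One row per town with the reference mean concentrations."""
    return pd.DataFrame([{"town": t, **m} for t, m in sr.TOWN_MEANS.items()])


@pytest.fixture
def small_survey() -> pd.DataFrame:
    """A tiny hand-written survey for screening/indices edge cases."""
    return pd.DataFrame({
        "sample_id": ["a1", "a2", "b1"],
        "town": ["A", "A", "B"],
        "x": [0.0, 100.0, 5000.0],
        "y": [0.0, 100.0, 5000.0],
        "Cd": [0.87, 1.46, 3.0],
        "Cu": [13.6, 120.0, 50.0],
        "Pb": [29.6, 69.0, 110.0],
        "Zn": [51.7, 87.6, 300.0],
    })
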