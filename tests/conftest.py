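import numpy as np
import pandas as pd
import pytest

from gwassess import GuidelineRegistry, SampleTable, SynthConfig, generate
from gwassess.ecological import ToxicityRegistry


@pytest.fixture(scope="session")
def registry():
    return GuidelineRegistry.default()


@pytest.fixture(scope="session")
def toxicity():
    return ToxicityRegistry.default()


@pytest.fixture(scope="session")
def synthetic_samples():
    """One deterministic synthetic table at the study's sample size."""
    return generate(SynthConfig(), seed=1)


@pytest.fixture
def tiny_samples():
    """Hand-written 4-station table with a missing-metal station."""
    df = pd.DataFrame(
        {
            "longitude": [90.19, 90.20, 90.21, 90.22],
            "latitude": [22.64, 22.66, 22.68, 22.70],
            "pH": [7.3, 7.8, 8.0, 7.5],
            "ec": [800.0, 1500.0, 3000.0, 1200.0],
            "tds": [512.0, 960.0, 1920.0, 768.0],
            "cd": [0.002, 0.010, np.nan, 0.129],
            "pb": [0.05, 0.20, np.nan, 0.271],
        },
        index=pd.Index(["A", "B", "C", "D"], name="station_id"),
    )
    return SampleTable(df)
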