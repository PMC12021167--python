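import numpy as np
import pandas as pd
import pytest

from tgua.config import DGPConfig


@pytest.fixture
def clean_config():
    """Small messiness-free cohort config (no dups/missing/outliers)."""
    return DGPConfig(n_patients=500, seed=11, dup_rate=0.0,
                     missing_rate=0.0, outlier_rate=0.0)


@pytest.fixture
def messy_config():
    """Default-messiness cohort config at a small n."""
    return DGPConfig(n_patients=800, seed=7)


@pytest.fixture
def toy_table():
    """Hand-sized table exercising every preprocessing rule."""
    return pd.DataFrame({
        "patient_id": ["a", "b", "c", "d", "d", "e", "f"],
        "record_index": [1, 1, 1, 2, 1, 1, 1],
        "age": [40.0, 55.0, 70.0, 60.0, 60.0, 45.0, np.nan],
        "sex": ["male", "female", "male", "female", "female", "male", "male"],
        "UA": [300.0, 320.0, np.nan, 410.0, 400.0, 350.0, 360.0],
        "TG": [1.2, 1.5, 1.8, 2.0, 2.1, np.nan, 1.4],
        "GLU": [4.0, np.nan, 8.0, 6.0, 6.5, 5.0, 5.5],
        "CREA": [80.0, 85.0, 90.0, 70.0, 72.0, 88.0, 95.0],
        "CHE": [7000.0, 7100.0, 7200.0, 7300.0, 7350.0, 7400.0, 7500.0],
        "CKMB": [2.0, 2.5, 1.5, 3.0, 3.1, 2.2, 2.4],
        "HGB": [150.0, 130.0, 140.0, np.nan, 120.0, 145.0, 135.0],
        "sodium": [141.0, 140.0, np.nan, 142.0, 141.5, 139.0, 140.5],
    })
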