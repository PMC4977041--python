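import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import didmort as dm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def worked_2x2_panel():
    """Two tracts, two years, saturated: tract A counts 100 -> 120 with PM
    10 -> 12; tract B counts 80 -> 80 with PM constant at 10; populations
    1,000.  The closed-form DiD slope is ln(1.2)/2."""
    return pd.DataFrame({
        "tract_id": ["A", "A", "B", "B"],
        "year": [2004, 2005, 2004, 2005],
        "age_group": "all",
        "deaths": [100, 120, 80, 80],
        "population": 1000,
        "pm25": [10.0, 12.0, 10.0, 10.0],
    })


@pytest.fixture(scope="session")
def clean_panel():
    """A moderate clean-scenario panel with its ground truth."""
    cfg = dm.ScenarioConfig(n_tracts=100, n_years=6, seed=42)
    panel, truth = dm.generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def no_spline_spec():
    return dm.ModelSpec(splines=())
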