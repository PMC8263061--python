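import dataclasses

import numpy as np
import pandas as pd
import pytest

from agemix.synthetic_data import default_scenarios, generate


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def small_linear_records(scenarios):
    """~2,200 partnerships from the linear-distributional truth."""
    cfg = dataclasses.replace(scenarios["linear_distributional"], n_respondents=1000)
    records, _ = generate(cfg, seed=42)
    return records


@pytest.fixture(scope="session")
def tiny_records():
    """50 deterministic records spanning both sexes, for scalar oracles."""
    rng = np.random.default_rng(7)
    a = rng.integers(15, 65, size=50)
    s = rng.integers(0, 2, size=50)
    p = np.clip(np.rint(a + rng.normal(0, 5, size=50)), 16, 80)
    return pd.DataFrame(
        {"respondent_age": a, "respondent_sex": s, "partner_age": p.astype(int)}
    )
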