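import numpy as np
import pandas as pd
import pytest

from seromics.io import NPXMatrix
from seromics.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return simulate_cohort(default_config(seed=7))


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(5, 1, size=(6, 3)),
        index=[f"s{i}" for i in range(6)],
        columns=["IL6", "IL18", "ADA"],
    )
    return NPXMatrix(vals)


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame(
        dict(
            sample_id=[f"s{i}" for i in range(6)],
            group=["NAFL"] * 3 + ["NASH"] * 3,
            fibrosis_stage=[0, 1, 2, 3, 4, 2],
            bmi=[24.0, 26.0, 30.0, 31.0, 28.0, 27.0],
            t2d=[False, True, False, True, False, True],
            hypertension=[False, False, True, True, False, True],
            age=[40, 50, 60, 45, 55, 65],
            sex=["F", "M", "F", "M", "F", "M"],
        )
    )
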