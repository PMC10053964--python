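import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mpclock as mp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230329)


@pytest.fixture
def blood_clock():
    return mp.builtin_blood_clock()


@pytest.fixture
def cardiac_clock():
    return mp.builtin_cardiac_clock()


def make_matrix(values: dict, index=None) -> mp.MethylationMatrix:
    """Small helper: dict of site -> list of percents to a matrix."""
    df = pd.DataFrame(values)
    if index is not None:
        df.index = index
    else:
        df.index = [f"S{i}" for i in range(len(df))]
    return mp.MethylationMatrix(df)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def random_panel_matrix(rng):
    """60 samples x full 31-site panel, uniform percents, no missing."""
    panel = mp.default_panel()
    df = pd.DataFrame(
        rng.uniform(0, 100, size=(60, len(panel))),
        columns=panel.site_ids,
        index=[f"S{i:03d}" for i in range(60)],
    )
    return mp.MethylationMatrix(df)
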