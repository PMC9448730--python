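import numpy as np
import pandas as pd
import pytest

import stepconn as sc


@pytest.fixture(scope="session")
def default_blueprint():
    return sc.make_blueprint(seed=0)


@pytest.fixture(scope="session")
def small_blueprint():
    """8x8x8 grid (~280 in-mask voxels): fast enough for cohort-level tests."""
    return sc.make_blueprint(grid_shape=(8, 8, 8), seed=0)


@pytest.fixture(scope="session")
def one_subject(default_blueprint):
    ts, motion = sc.simulate_subject(default_blueprint, None, seed=1)
    return ts, motion


def cohort_table(specs):
    return pd.DataFrame(
        [{"group": s.group, "age": s.age, "sex": s.sex, **s.clinical} for s in specs]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
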