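import numpy as np
import pandas as pd
import pytest

from opilio.reference import SURVIVAL_PARAMS
from opilio.simulate import DesignSpec, gen_survival_experiment


@pytest.fixture(scope="session")
def year1_dataset():
    """One design-scale survival experiment simulated from the year-1
    best-fit parameters (9 cells x 5 inserts x 20 larvae, 49-day horizon)."""
    return gen_survival_experiment(DesignSpec(seed=20240801), SURVIVAL_PARAMS[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_group_table(rng):
    """Two multivariate-normal groups with a real location difference."""
    x = rng.normal(size=(20, 4))
    x[10:] += [1.0, 0.0, 0.5, 0.0]
    tbl = pd.DataFrame(x, columns=list("wxyz"))
    groups = np.array(["a"] * 10 + ["b"] * 10)
    return tbl, groups
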