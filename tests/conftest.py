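import numpy as np
import pytest

from krillab import model as mc
from krillab import synthetic as syn


@pytest.fixture(scope="session")
def bh_params():
    return mc.PRESETS["BH"]


@pytest.fixture(scope="session")
def rk_params():
    return mc.PRESETS["RK"]


@pytest.fixture(scope="session")
def small_study():
    """Noise-free 8-year RK study: fast enough for unit tests."""
    cfg = syn.SyntheticConfig(n_years=8, seed=3, preset="RK", obs_noise_sd=0.0)
    return syn.make_study(cfg)


@pytest.fixture(scope="session")
def toy_design():
    """Small standardized two-block regression design with known truth."""
    from krillab import fusedlasso as fl

    rng = np.random.default_rng(42)
    m, k = 10, 3
    X = rng.normal(size=(m, 2 * k))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    a_true = np.array([1.0, 1.0, 0.0, -0.5, 0.0, 0.0])
    y = 0.3 + X @ a_true + 0.1 * rng.normal(size=m)
    design = fl.FactorDesign(
        X=X, y=y, years=np.arange(m), factors=("A", "B"), offsets=(0, 1, 2),
        means=np.zeros(2 * k), sds=np.ones(2 * k),
    )
    return design, a_true
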