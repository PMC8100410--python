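import numpy as np
import pytest

from adseverity.synthetic import make_cohort, make_multitask_problem, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(shape=(32, 32, 16), n_blobs=3, noise_sigma=15.0, seed=3)


@pytest.fixture(scope="session")
def small_multitask():
    return make_multitask_problem(d=20, m=4, n_per_task=40, s_shared=3,
                                  k_outlier=1, noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(n_patients=300, n_features=40, effect_size=3.0, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
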