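import numpy as np
import pytest

from trajrecur import SyntheticConfig, default_registry_config, generate_cohort
from trajrecur.nhpp import NHPPParams
from trajrecur.splines import make_spec
from trajrecur.synthetic import TrajectoryShape


@pytest.fixture(scope="session")
def registry_config():
    return default_registry_config()


@pytest.fixture(scope="session")
def small_cohort(registry_config):
    """200-subject cohort from the default 8-class configuration."""
    return generate_cohort(registry_config, n_subjects=200, seed=11)


@pytest.fixture(scope="session")
def two_class_config():
    """Well-separated two-class configuration (means 6 and 11)."""
    return SyntheticConfig(
        K=2,
        pi=np.array([0.6, 0.4]),
        class_trajectories=[
            TrajectoryShape("stable", (6.0,)),
            TrajectoryShape("stable", (11.0,)),
        ],
        sigma_b=np.array([0.1, 0.1]),
        sigma_e=0.2,
        nhpp=NHPPParams(eta=400.0, beta_shape=1.3, gamma=np.array([np.log(2.0)])),
        seed=0,
    )


@pytest.fixture(scope="session")
def two_class_cohort(two_class_config):
    return generate_cohort(two_class_config, n_subjects=300, seed=3)


@pytest.fixture(scope="session")
def pooled_spec(small_cohort):
    cohort, _ = small_cohort
    times = np.concatenate([s.times for s in cohort.series.values()])
    return make_spec(times, 10, "equipotent")
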