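import numpy as np
import pytest

from conntraj import (
    GroundTruthSpec,
    estimate_connectivity,
    fit_normative,
    simulate_normative_cohort,
)
from conntraj.regions import default_motor_labels


@pytest.fixture(scope="session")
def small_normative():
    """A small fitted normative model (R=8, n=40, T=250) shared across tests."""
    spec = GroundTruthSpec(n_regions=8, subject_jitter=60, seed=11)
    rng = np.random.default_rng(11)
    cohort = simulate_normative_cohort(spec, 40, 250, rng=rng)
    mats = [estimate_connectivity(ts) for ts in cohort]
    model = fit_normative(mats, region_labels=spec.region_labels)
    return spec, cohort, mats, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, scale=1.0):
    """Well-conditioned random SPD matrix."""
    A = rng.normal(size=(n, n))
    return scale * (A @ A.T + n * np.eye(n))


@pytest.fixture(scope="session")
def motor_labels():
    return default_motor_labels(45)
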