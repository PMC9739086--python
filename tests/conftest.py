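import numpy as np
import pytest

from wristkin import (
    FusionConfig,
    NoiseModel,
    PipelineConfig,
    discus_throw_preset,
    simulate_truth,
    stationary_preset,
    truth_to_imu,
)

FS = 500.0  # capture clock, Hz


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def discus_truth():
    return simulate_truth(discus_throw_preset(), FS)


@pytest.fixture(scope="session")
def discus_capture(discus_truth):
    """Noise-free forward-modelled capture of the default throw."""
    return truth_to_imu(discus_truth, NoiseModel.zero())


@pytest.fixture(scope="session")
def stationary_capture():
    truth = simulate_truth(stationary_preset(6.0), FS)
    return truth_to_imu(truth, NoiseModel.zero())


@pytest.fixture
def fusion_cfg():
    return FusionConfig()


@pytest.fixture
def recon_cfg():
    return PipelineConfig.reconstruction()


def random_unit_quaternions(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def fit_circle_radius(xy):
    """Least-squares (Kasa) circle fit; returns the fitted radius."""
    xy = np.asarray(xy, float)
    A = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    c, *_ = np.linalg.lstsq(A, (xy ** 2).sum(axis=1), rcond=None)
    return float(np.sqrt(c[2] + c[0] ** 2 + c[1] ** 2))
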