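import numpy as np
import pytest

from mlmm.synthetic import (
    catalytic_environment,
    default_ground_truth,
    generate_conformers,
    generate_environment,
)


@pytest.fixture(scope="session")
def gt():
    return default_ground_truth()


@pytest.fixture(scope="session")
def conformers(gt):
    regions, rcs = generate_conformers(gt, 40, seed=11)
    return regions, rcs


@pytest.fixture(scope="session")
def droplet(gt):
    region = gt.build_geometry(0.0)
    return generate_environment(region=region, seed=3, n_charges=30)


@pytest.fixture(scope="session")
def cat_env(gt):
    return catalytic_environment(gt, seed=18)


@pytest.fixture(scope="session")
def trained(gt):
    """Models trained once per session on the synthetic reference data."""
    from mlmm.workflows import train_models

    return train_models(gt, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = 5.0 * rng.standard_normal(3)
    return q, t
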