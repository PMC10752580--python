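import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import entrain as en

settings.register_profile(
    "default", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_ds():
    """Default planted trajectory dataset: 3 drivers among 15 ligands."""
    return en.simulate_trajectory_dataset(seed=0)


@pytest.fixture(scope="session")
def planted_design(planted_ds):
    ds = planted_ds
    branch = en.make_branch(ds.expression, ds.annotation, "branch0")
    cov = en.branch_covariance(branch)
    training = en.select_training_genes(cov)
    return en.build_design(ds.prior, training, list(ds.prior.ligand_ids), cov)


@pytest.fixture(scope="session")
def planted_branch(planted_ds):
    return en.make_branch(planted_ds.expression, planted_ds.annotation,
                          "branch0")


@pytest.fixture(scope="session")
def velocity_ds():
    return en.simulate_velocity_dataset(seed=0)


@pytest.fixture(scope="session")
def small_branch():
    """Tiny deterministic branch for closed-form checks."""
    rng = np.random.default_rng(7)
    n, g = 40, 12
    matrix = rng.uniform(0, 2, (n, g))
    tau = np.linspace(0, 1, n)
    return en.TrajectoryBranch(matrix, tau,
                               [f"c{i}" for i in range(n)],
                               [f"g{j}" for j in range(g)], "toy")
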