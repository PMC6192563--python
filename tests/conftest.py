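import numpy as np
import pytest

from conndyn import CohortSpec, StructuralConnectome, WilsonCowanParams


def make_connectome(n=10, density=0.3, seed=0, scale=1.0, extent=100.0):
    """Small random connectome for unit tests (not the cohort generator)."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    w = np.where(rng.random(len(iu[0])) < density,
                 rng.lognormal(0.0, 1.0, len(iu[0])) * scale, 0.0)
    A = np.zeros((n, n))
    A[iu] = w
    A = A + A.T
    return StructuralConnectome(
        labels=[f"R{i:03d}" for i in range(n)],
        A=A,
        centroids=rng.uniform(0.0, extent, size=(n, 3)),
        volumes=rng.uniform(1000.0, 8000.0, size=n),
    )


@pytest.fixture
def small_conn():
    return make_connectome()


@pytest.fixture
def single_node():
    return StructuralConnectome(labels=["R000"], A=np.zeros((1, 1)),
                                centroids=np.zeros((1, 3)), volumes=np.ones(1))


@pytest.fixture
def params_nonoise():
    return WilsonCowanParams(sigma=0.0)


@pytest.fixture
def tiny_cohort_spec():
    return CohortSpec(n_subjects=3, n_regions=12, seed=5)
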