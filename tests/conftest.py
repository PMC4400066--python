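import numpy as np
import pytest

from dwieval import CanonicalKernel, GradientTable, default_basis, electrostatic_sphere
from dwieval.simulation import DEFAULT_KERNEL, simulation_gradient_table


@pytest.fixture(scope="session")
def kernel() -> CanonicalKernel:
    return DEFAULT_KERNEL


@pytest.fixture(scope="session")
def gtab150(kernel) -> GradientTable:
    """150-direction single-shell table at b = 2000 s/mm^2."""
    return simulation_gradient_table(2000.0, 150)


@pytest.fixture(scope="session")
def basis100(kernel):
    """Small fascicle basis shared across tests to keep runtimes down."""
    return default_basis(kernel, 2000.0, n=100)


@pytest.fixture(scope="session")
def gtab_with_b0(gtab150) -> GradientTable:
    """gtab150 preceded by 10 b0 volumes."""
    bvals = np.concatenate([np.zeros(10), gtab150.bvals])
    bvecs = np.vstack([np.zeros((10, 3)), gtab150.bvecs])
    return GradientTable(bvecs, bvals)
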