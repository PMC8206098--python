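import numpy as np
import pytest
from scipy import sparse

from neuroevo.reservoir import Reservoir, ReservoirParams


@pytest.fixture(scope="session")
def tiny_params() -> ReservoirParams:
    """Small, fast reservoir geometry for unit tests."""
    return ReservoirParams(n_neuron=40, t_train=30.0, t_signal=30.0,
                           t_evaluation=10.0)


def make_decoupled_reservoir(n: int, x0, dt: float = 0.1,
                             params: ReservoirParams | None = None) -> Reservoir:
    """A reservoir with Q = 0 and B = 0, so the dynamics is pure leak decay."""
    params = params or ReservoirParams(n_neuron=n, dt=dt, t_train=30.0,
                                       t_signal=30.0, t_evaluation=10.0)
    return Reservoir(
        Q=sparse.csr_array((n, n)),
        F=np.zeros((1, n)),
        B=np.zeros((n, 1)),
        x=np.full(n, float(x0)) if np.isscalar(x0) else np.asarray(x0, float),
        params=params,
    )
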