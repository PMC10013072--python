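import warnings

import numpy as np
import pytest

from rotorpool.stationary import find_stationary_states

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        module="scipy.optimize._zeros_py")

SIGMA = 5.0
# reference three-root point of the layer dynamics
R1_REF, R2_REF = 0.9, 2.0


@pytest.fixture(scope="session")
def branches_ref():
    """The three stationary branches at (0.9, 2.0), sigma = 5."""
    branches = find_stationary_states(R1_REF, R2_REF, SIGMA)
    assert len(branches) == 3
    return branches


@pytest.fixture(scope="session")
def spectra_ref(branches_ref):
    """Discrete spectra + classifications of the three reference branches."""
    from rotorpool.spectrum import classify_stability, discrete_spectrum

    out = {}
    for br in branches_ref:
        eigs = discrete_spectrum(br)
        res = classify_stability(br, discrete=eigs)
        out[br.label] = res
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def burst_ts_network():
    """Full-system burst trajectory, microscopic engine (N = 1000)."""
    from rotorpool.model import ModelParams, ResourceState
    from rotorpool.network import init_population, simulate

    params = ModelParams(N=1000)
    pop = init_population(1000, seed=42)
    return simulate(pop, ResourceState(r=params.s + 0.4, lam=0.15), params,
                    t_end=2500.0, dt_out=0.5)


@pytest.fixture(scope="session")
def burst_ts_reduced():
    """Full-system burst trajectory, coupled reduced OA engine (M = 201)."""
    from rotorpool.model import ModelParams, ResourceState
    from rotorpool.slowfast import simulate_reduced_oa

    params = ModelParams()
    return simulate_reduced_oa(params, res0=ResourceState(r=params.s + 0.4, lam=0.15),
                               t_end=2500.0, M=201)
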