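import numpy as np
import pytest

from lvshape.mesh import LatticeTopology
from lvshape import synthetic


@pytest.fixture(scope="session")
def fine_topo():
    """Default-resolution lattice (accuracy-sensitive geometry tests)."""
    return LatticeTopology()


@pytest.fixture(scope="session")
def coarse_topo():
    """Coarse lattice for speed-sensitive pipeline tests."""
    return LatticeTopology(n_circ=24, n_long=16)


@pytest.fixture(scope="session")
def template(fine_topo):
    return synthetic.make_template(synthetic.TemplateParams(), fine_topo)


@pytest.fixture(scope="session")
def coarse_template(coarse_topo):
    return synthetic.make_template(synthetic.TemplateParams(), coarse_topo)


def survival_toy(seed=0, n=300, beta=None, base_rate=0.05, censor_rate=0.12,
                 horizon=16.0, p=10):
    """Right-censored proportional-hazards draw used across Cox tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    b = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    eta = X @ b
    t_ev = rng.exponential(np.exp(-eta) / base_rate)
    c = np.minimum(rng.exponential(1.0 / censor_rate, n), horizon)
    time = np.minimum(t_ev, c)
    event = (t_ev <= c).astype(int)
    return X, time, event
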