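import numpy as np
import pytest

from causalflow import (GroundTruthNetwork, default_network,
                        simulate_subject_timeseries)
from causalflow.flow import PreferredFlow, preferred_index


def make_var_pair(weight: float, T: int, seed: int, quadratic: bool = False):
    """Two-series system: x white noise, y driven by x at lag 1."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=T)
    e = rng.normal(size=T)
    y = np.empty(T)
    y[0] = e[0]
    if quadratic:
        y[1:] = weight * (x[:-1] - x.mean()) ** 2 + e[1:]
    else:
        y[1:] = weight * x[:-1] + e[1:]
    return x, y


def flow_from_matrix(p: np.ndarray, region_ids=None) -> PreferredFlow:
    return PreferredFlow(p_matrix=p, index=preferred_index(p),
                         region_ids=region_ids)


def random_valid_preferred(n: int, rng) -> np.ndarray:
    """Random matrix satisfying the antisymmetry contract."""
    p = np.full((n, n), 0.5)
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0, 1, size=len(iu[0]))
    p[iu] = vals
    p[(iu[1], iu[0])] = 1.0 - vals
    return p


@pytest.fixture
def two_region_null_network():
    return GroundTruthNetwork(n_regions=2, coupling=np.zeros((2, 2)))


@pytest.fixture
def small_cohort_flows():
    """Twelve fitted flows from one network: a quick identical-groups pool."""
    from causalflow import InformationFlow

    net = default_network(n_regions=5, reciprocal_pairs=((0, 1),),
                          extra_edges=((2, 3, 0.4),))
    flows = []
    for s in range(12):
        ts = simulate_subject_timeseries(net, 120, 3.0, seed=500 + s)
        flows.append(InformationFlow(ts).fit().flow)
    return flows
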