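import numpy as np
import pytest

import genebond as gb
from genebond import params


@pytest.fixture
def fig_example_net():
    """The worked two-reaction example network A + B <-> C <-> 2 D."""
    return gb.NetworkSpec(
        [
            gb.SpeciesSpec("A", K=1.0, x0=1.0),
            gb.SpeciesSpec("B", K=2.0, x0=1.0),
            gb.SpeciesSpec("C", K=3.0, x0=0.0),
            gb.SpeciesSpec("D", K=4.0, x0=0.0),
        ],
        [
            gb.ReactionSpec("r1", 1.5, {"A": 1, "B": 1}, {"C": 1}),
            gb.ReactionSpec("r2", 0.7, {"C": 1}, {"D": 2}),
        ],
    )


@pytest.fixture(scope="session")
def default_gene():
    return params.default_gene_params("g1")


@pytest.fixture(scope="session")
def single_gene_steady_state(default_gene):
    """Steady state of the induced single gene at default pools (computed once)."""
    net = gb.build_gene_expression(default_gene, pools=params.default_pools())
    x = gb.find_steady_state(net)
    return net, x


@pytest.fixture(scope="session")
def repressilator_timecourse():
    """Default repressilator run, shared by the oscillation tests."""
    spec = params.default_repressilator_spec()
    net = gb.build_repressilator(spec)
    tc = gb.integrate(
        net,
        net.initial_state(params.REPRESSILATOR_IC),
        t_span=(0.0, 2500.0),
        t_eval=np.linspace(0.0, 2500.0, 5001),
    )
    return net, tc


def chain_steady_flux(kf: float, kr: float, m: int, c_first: float, c_last: float, A: float) -> float:
    """Independent oracle: exact steady-state flux of the explicit m-step chain.

    Solves the linear steady-state system of the intermediates X1..X_{m-1}
    analytically by telescoping: v * sum_k a^k b^(m-1-k) = a^m c1 - b^m cn
    with a = kf*A, b = kr.
    """
    a, b = kf * A, kr
    S = sum(a**k * b ** (m - 1 - k) for k in range(m))
    return (a**m * c_first - b**m * c_last) / S
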