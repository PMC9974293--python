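"""Shared simulation fixtures.

The expensive converged-beat simulations are session-scoped so the whole
suite runs each study condition once: the default uniform tube, the
near-linear matched tube (amplitude-level reflection oracle), the
Murray-matched tree, the single-reflector echo fixture, and the supine /
standing pair on the bundled arterial tree.
"""

import pytest

from pulsewave.fixtures import default_inflow, make_canonical_networks
from pulsewave.network import SimConfig
from pulsewave.posture import STANDING, SUPINE, apply_posture
from pulsewave.solver import simulate_beats

RHO = 1050.0


@pytest.fixture(scope="session")
def uniform_beat():
    net = make_canonical_networks("uniform_tube")
    res = simulate_beats(net, default_inflow("uniform_tube"), 0.0, SimConfig())
    return net, res


@pytest.fixture(scope="session")
def stiff_matched_beat():
    """Stiff, inviscid, quasi-static-compliance tube: the construction in
    which the matched termination is reflection-free at amplitude level."""
    net = make_canonical_networks("uniform_tube", SV_ml=5.0, terminal_tau=600.0,
                                  c_op=10.0, p_mean_mmhg=20.0)
    inf = default_inflow("uniform_tube", SV_ml=5.0)
    res = simulate_beats(net, inf, 0.0, SimConfig(blood_viscosity=1e-7))
    return net, res


@pytest.fixture(scope="session")
def murray_beat():
    net = make_canonical_networks("murray_tree")
    res = simulate_beats(net, default_inflow("murray_tree"), 0.0, SimConfig())
    return net, res


@pytest.fixture(scope="session")
def reflector_beat():
    net = make_canonical_networks("single_reflector")
    res = simulate_beats(net, default_inflow("single_reflector"), 0.0,
                         SimConfig(cfl=0.98))
    return net, res


@pytest.fixture(scope="session")
def mini_pair():
    """Converged supine and standing beats on the bundled arterial tree."""
    base = make_canonical_networks("mini_aorta")
    inf = default_inflow("mini_aorta")
    net_sup, inf_sup, _ = apply_posture(base, inf, SUPINE)
    res_sup = simulate_beats(net_sup, inf_sup, SUPINE, SimConfig())
    net_std, inf_std, app = apply_posture(base, inf, STANDING)
    res_std = simulate_beats(net_std, inf_std, STANDING, SimConfig())
    assert res_sup.report.converged and res_std.report.converged
    return {"net_sup": net_sup, "res_sup": res_sup,
            "net_std": net_std, "res_std": res_std, "app": app,
            "base": base, "inflow": inf}

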