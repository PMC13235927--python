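import numpy as np
import pytest

import plasmidnet as pn
from plasmidnet.experiments import make_initial_conditions, scaled_parameters


@pytest.fixture(scope="session")
def table2():
    return pn.table2_parameters()


@pytest.fixture(scope="session")
def scaled():
    """Reduced-community preset: K=2000, conjugation rescaled to keep gamma*K."""
    return scaled_parameters()


@pytest.fixture(scope="session")
def canonical_networks():
    """All nine factorial (I, P) cells, keyed by (I structure, P structure)."""
    cells = {}
    for i_s in ("full", "nested", "modular"):
        for p_s in ("full", "modular", "hub"):
            I = pn.build_infection_network(i_s)
            P = pn.build_compatibility_network(p_s, 4, 0 if p_s == "hub" else None)
            cells[(i_s, p_s)] = (I, P)
    return cells


@pytest.fixture(scope="session")
def one_host_two_plasmids():
    """Minimal fully connected system used for the worked transfer example."""
    I = pn.InfectionNetwork(np.ones((1, 2), dtype=np.int8), "full")
    P = pn.build_compatibility_network("full", 2)
    return I, P


def make_scaled_cell(i_s, p_s, params, plasmid_free=200, mono=10, hub=0):
    I = pn.build_infection_network(i_s)
    P = pn.build_compatibility_network(p_s, 4, hub if p_s == "hub" else None)
    init = make_initial_conditions(I, plasmid_free, mono)
    system = pn.compile_system(I, P, params)
    return I, P, init, system
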