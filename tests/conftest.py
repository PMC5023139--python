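import numpy as np
import pytest

import fluxforest as ff


@pytest.fixture(scope="session")
def ecoli():
    return ff.load_reference_model("ecoli_ccm")


@pytest.fixture(scope="session")
def bsubtilis():
    return ff.load_reference_model("bsubtilis_ccm")


@pytest.fixture(scope="session")
def two_source():
    return ff.make_two_source_fixture(0.3)


def flux_state(network, net, exch=None):
    net = np.asarray(net, dtype=float)
    if exch is None:
        exch = np.zeros_like(net)
    return ff.FluxState(network, net, np.asarray(exch, dtype=float))


@pytest.fixture(scope="session")
def toy_states():
    """Hand-built steady-state flux maps for every toy network."""
    states = {}

    chain = ff.toy_chain()
    states["chain"] = (chain, flux_state(chain, [10, 10, 10]))

    cond = ff.toy_condensation()
    states["condensation"] = (cond, flux_state(cond, [10] * 5))

    cyc = ff.make_cycle_fixture()
    # upt, anap, cs, cleave, out_ac, out_oax, out_co
    states["cycle"] = (cyc.network, flux_state(cyc.network, [10, 2, 3, 3, 7, 2, 6]))

    sym = ff.make_symmetric_fixture()
    states["symmetric"] = (
        sym.network,
        flux_state(sym.network, [10, 5, 5, 5], [0, 2.5, 0, 0]),
    )

    two = ff.make_two_source_fixture()
    states["two_source"] = (two.network, flux_state(two.network, [3, 7, 10]))
    return states
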