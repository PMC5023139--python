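"""Label-propagation correctness: EMU cascade vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxforest as ff
from fluxforest.emu import _conv_batch
from fluxforest.errors import SimulationError


# ---------------------------------------------------------------------------
# convolution

def test_convolve_identity_and_binomial():
    a = np.array([0.2, 0.5, 0.3])
    np.testing.assert_allclose(ff.convolve(a, [1.0]), a)
    np.testing.assert_allclose(
        ff.convolve([0.5, 0.5], [0.5, 0.5]), [0.25, 0.5, 0.25]
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=7),
    st.lists(st.floats(0.01, 1.0), min_size=1, max_size=7),
)
def test_convolve_matches_polynomial_multiplication(a, b):
    a = np.array(a) / np.sum(a)
    b = np.array(b) / np.sum(b)
    got = ff.convolve(a, b)
    expect = np.polynomial.polynomial.polymul(a, b)
    assert len(got) == len(a) + len(b) - 1
    np.testing.assert_allclose(got, expect, atol=1e-12)
    # mass conservation
    assert got.sum() == pytest.approx(1.0, abs=1e-12)


def test_conv_batch_matches_scalar_convolution():
    rng = np.random.default_rng(0)
    A = rng.dirichlet(np.ones(4), size=6)
    B = rng.dirichlet(np.ones(3), size=6)
    got = _conv_batch(A, B)
    for i in range(6):
        np.testing.assert_allclose(got[i], np.convolve(A[i], B[i]), atol=1e-14)


# ---------------------------------------------------------------------------
# decomposition structure

def test_chain_decomposition_minimal():
    net = ff.toy_chain()
    sys = ff.emu_decompose(net, [("c", (0, 1))])
    keys = set(sys.terms)
    assert keys == {("c", (0, 1)), ("b", (0, 1))}
    assert sys.max_size == 2


def test_condensation_introduces_convolution():
    net = ff.toy_condensation()
    sys = ff.emu_decompose(net, [("c", (0, 1, 2, 3))])
    conv_terms = [
        t
        for lv in sys.levels
        for (_, _, _, sources) in lv["inputs"]
        for t in [sources]
        if len(t) > 1
    ]
    assert conv_terms, "expected at least one convolution term"


def test_unreachable_target_rejected():
    net = ff.toy_chain()
    with pytest.raises(SimulationError, match="outside"):
        ff.emu_decompose(net, [("c", (0, 5))])
    with pytest.raises(SimulationError, match="unknown metabolite"):
        ff.emu_decompose(net, [("zz", (0,))])


def test_ecoli_decomposition_scales(ecoli):
    sys = ff.emu_decompose(ecoli.network, ecoli.spec("gcms").targets)
    assert sys.max_size <= 6
    assert sys.n_emus < 500


# ---------------------------------------------------------------------------
# simulation basics

def test_unlabeled_substrate_gives_unlabeled_mdvs(toy_states):
    net, fs = toy_states["condensation"]
    tracer = ff.parse_label(
        {"substrate": "s", "natural_abundance": 0.0,
         "components": [{"fraction": 1.0, "positions": []}]},
        4,
    )
    sys = ff.emu_decompose(net, [("c", (0, 1, 2, 3)), ("y", (0, 1))])
    res = ff.simulate_mdvs(sys, fs, tracer)
    for mdv in res.values():
        assert mdv.fractions[0] == pytest.approx(1.0, abs=1e-12)


def test_linear_chain_passes_tracer_through(toy_states):
    net, fs = toy_states["chain"]
    tracer = ff.parse_label(
        {"substrate": "s", "natural_abundance": 0.0,
         "components": [{"fraction": 0.6, "positions": [1, 2]},
                        {"fraction": 0.4, "positions": []}]},
        2,
    )
    sys = ff.emu_decompose(net, [("c", (0, 1))])
    res = ff.simulate_mdvs(sys, fs, tracer)
    np.testing.assert_allclose(
        res[("c", (0, 1))].fractions, [0.4, 0.0, 0.6], atol=1e-12
    )


def test_two_source_closed_form_mixing(two_source):
    """MDV(p) = f MDV(a) + (1-f) MDV(b); mixing fraction recovered to 1e-9."""
    net = two_source.network
    f = 0.3
    ua = 10.0
    ub = ua * (1 - f) / f
    fs = ff.FluxState(net, np.array([ua, ub, ua + ub]), np.zeros(3))
    sys = ff.emu_decompose(net, [("p", (0, 1)), ("p", (0,))])
    res = ff.simulate_mdvs(sys, fs, two_source.tracer)
    exp = f * two_source.expectations["mdv_a"] + (1 - f) * two_source.expectations["mdv_b"]
    np.testing.assert_allclose(res[("p", (0, 1))].fractions, exp, atol=1e-9)
    # invert: the M+1 fraction IS the mixing fraction
    assert res[("p", (0, 1))].fractions[1] == pytest.approx(f, abs=1e-9)


def test_scaling_invariance(ecoli):
    """Multiplying all fluxes by a constant leaves MDVs unchanged."""
    tracer = ff.glucose_tracer("1")
    spec = ecoli.spec("gcms")
    sys = ff.emu_decompose(ecoli.network, spec.targets)
    net = ff.sample_net_fluxes(ecoli.network, 3, seed=21)
    exch = ff.assign_exchange(ecoli.network, net, 1.0, seed=22)
    coh = ff.FluxCohort(ecoli.network, net, exch)
    a = sys.simulate(coh.fwd, coh.bwd, tracer)
    b = sys.simulate(coh.fwd * 7.3, coh.bwd * 7.3, tracer)
    for k in a:
        np.testing.assert_allclose(a[k], b[k], atol=1e-10)


def test_exchange_equilibration_limit():
    """As exchange -> infinity on a reversible pair, fragment MDVs converge."""
    fx = ff.make_symmetric_fixture()
    net = fx.network
    sys = ff.emu_decompose(net, [("a", (0, 1)), ("f", (0, 1))])

    def gap(exch):
        fs = ff.FluxState(
            net, np.array([10.0, 5.0, 5.0, 5.0]), np.array([0.0, exch, 0.0, 0.0])
        )
        res = ff.simulate_mdvs(sys, fs, fx.tracer)
        return np.abs(
            res[("a", (0, 1))].fractions - res[("f", (0, 1))].fractions
        ).max()

    gaps = [gap(e) for e in (0.0, 1.0, 100.0, 1e6)]
    assert all(x >= y - 1e-12 for x, y in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-3 < gaps[0]


def test_zero_throughput_measured_pool_raises(ecoli):
    """A flux map that empties a measured pool is rejected, not NaN-ed."""
    net = np.zeros(len(ecoli.network.reactions))
    ju = ecoli.network.reaction_index
    # route everything straight to pyruvate output; TCA off
    for rid, v in [("upt", 10.0), ("pgi", 10.0), ("pfk", 10.0), ("fba", 10.0),
                   ("tpi", 10.0), ("gap", 20.0), ("eno", 20.0), ("pyk", 20.0),
                   ("out_pyr", 20.0)]:
        net[ju(rid)] = v
    sys = ff.emu_decompose(ecoli.network, ecoli.spec("gcms").targets)
    with pytest.raises(SimulationError, match="zero throughput"):
        sys.simulate(np.maximum(net, 0)[None, :], np.maximum(-net, 0)[None, :],
                     ff.glucose_tracer("1"))


# ---------------------------------------------------------------------------
# oracle equivalence (chain, condensation, cycle, symmetric, two-source)

def _targets_for(network):
    """All full molecules plus a couple of sub-fragments."""
    targets = []
    for m, n in network.metabolites.items():
        if m in network.substrates:
            continue
        targets.append((m, tuple(range(n))))
        if n >= 2:
            targets.append((m, (0,)))
            targets.append((m, (n - 2, n - 1)))
    return sorted(set(targets))


@pytest.mark.parametrize(
    "name", ["chain", "condensation", "cycle", "symmetric", "two_source"]
)
def test_emu_matches_brute_force_oracle(name, toy_states):
    network, fs = toy_states[name]
    tracer = ff.parse_label(
        {"substrate": "s", "natural_abundance": 0.011,
         "components": [{"fraction": 0.55, "positions": [1]},
                        {"fraction": 0.45, "positions": []}]},
        network.metabolites,
    ) if "s" in network.substrates else ff.make_two_source_fixture().tracer
    targets = _targets_for(network)
    sys = ff.emu_decompose(network, targets)
    got = ff.simulate_mdvs(sys, fs, tracer)
    expect = ff.brute_force_isotopomers(network, fs, tracer, targets)
    for t in targets:
        np.testing.assert_allclose(
            got[t].fractions, expect[t], atol=1e-8,
            err_msg=f"{name}: fragment {t}",
        )


def test_symmetric_metabolite_mass_profile_reversal_invariant(toy_states):
    """A symmetric pool's fragment MDV equals that of the reversed fragment."""
    network, fs = toy_states["cycle"]
    tracer = ff.parse_label(
        {"substrate": "s", "natural_abundance": 0.0,
         "components": [{"fraction": 1.0, "positions": [1]}]},
        2,
    )
    sys = ff.emu_decompose(network, [("oax", (0,)), ("oax", (1,))])
    res = ff.simulate_mdvs(sys, fs, tracer)
    np.testing.assert_allclose(
        res[("oax", (0,))].fractions, res[("oax", (1,))].fractions, atol=1e-12
    )


def test_brute_force_refuses_large_state_spaces():
    letters = "abcdefghijklmnopq"  # 17 carbons -> 2^17 isotopomer states
    net = ff.parse_network(
        f"@substrate s\nr1: s ({letters}) -> b ({letters})\nout_b: b ({letters}) ->"
    )
    fs = ff.FluxState(net, np.array([10.0, 10.0]), np.zeros(2))
    tracer = ff.parse_label(
        {"substrate": "s", "components": [{"fraction": 1.0, "positions": [1]}]},
        17,
    )
    with pytest.raises(SimulationError, match="too large"):
        ff.brute_force_isotopomers(net, fs, tracer, [("b", (0, 1))])
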