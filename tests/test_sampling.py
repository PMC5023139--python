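import numpy as np
import pytest

import fluxforest as ff
from fluxforest.errors import InfeasibleError, SamplingError
from fluxforest.ratios import RatioDefinition, RatioTerm
from fluxforest.sampling import flux_bounds


def test_chain_forced_by_stoichiometry():
    net = ff.toy_chain()
    v0 = ff.initial_flux(net)
    assert np.allclose(v0, [10.0, 10.0, 10.0], atol=1e-6)
    # zero-dimensional null space: every sample equals the initial solution
    s = ff.sample_net_fluxes(net, 5, seed=0)
    assert np.allclose(s, v0[None, :], atol=1e-6)


def test_diamond_min_norm_splits_evenly():
    net = ff.toy_diamond()
    v0 = ff.initial_flux(net)
    ju, jv = net.reaction_index("u"), net.reaction_index("v")
    assert v0[ju] == pytest.approx(5.0, abs=1e-5)
    assert v0[jv] == pytest.approx(5.0, abs=1e-5)


def test_ecoli_initial_flux_residual(ecoli):
    v0 = ff.initial_flux(ecoli.network)
    S = ecoli.network.stoichiometric_matrix()
    assert np.abs(S @ v0).max() < 1e-6
    assert v0[ecoli.network.reaction_index("upt")] == pytest.approx(10.0)


def test_infeasible_constraints_raise(ecoli):
    c = np.zeros(len(ecoli.network.reactions))
    c[ecoli.network.reaction_index("pgi")] = 1.0
    with pytest.raises(InfeasibleError):
        ff.initial_flux(ecoli.network, extra_constraints=[(c, 500.0)])


def test_sample_invariants_bulk(ecoli):
    """Every sample satisfies S v = 0, bounds, and irreversibility."""
    n = 10000
    s = ff.sample_net_fluxes(ecoli.network, n, seed=5)
    assert s.shape == (n, len(ecoli.network.reactions))
    S = ecoli.network.stoichiometric_matrix()
    assert np.abs(S @ s.T).max() < 1e-6
    lb, ub = flux_bounds(ecoli.network)
    ju = ecoli.network.reaction_index("upt")
    assert np.allclose(s[:, ju], 10.0, atol=1e-6)
    assert np.all(s >= lb[None, :] - 1e-6)
    assert np.all(s <= ub[None, :] + 1e-6)


def test_sampling_is_seed_reproducible(ecoli):
    a = ff.sample_net_fluxes(ecoli.network, 50, seed=9)
    b = ff.sample_net_fluxes(ecoli.network, 50, seed=9)
    np.testing.assert_array_equal(a, b)
    c = ff.sample_net_fluxes(ecoli.network, 50, seed=10)
    assert not np.allclose(a, c)


def test_diamond_branch_ratio_spans_range():
    net = ff.toy_diamond()
    s = ff.sample_net_fluxes(net, 1000, seed=1)
    r = s[:, net.reaction_index("u")] / 10.0
    assert r.min() < 0.05 and r.max() > 0.95


def test_exchange_law_bounds(ecoli):
    net = ff.sample_net_fluxes(ecoli.network, 200, seed=3)
    exch = ff.assign_exchange(ecoli.network, net, exch_bound=10.0, seed=4)
    rev = ecoli.network.reversible_mask
    assert np.all(exch[:, ~rev] == 0.0)
    mag = np.where(np.abs(net) < 1e-9, 10.0 * 1e-3, np.abs(net))
    assert np.all(exch[:, rev] <= 10.0 * mag[:, rev] + 1e-12)
    assert np.all(exch >= 0.0)
    # fwd - bwd = net exactly
    fwd = exch + np.maximum(net, 0.0)
    bwd = exch + np.maximum(-net, 0.0)
    np.testing.assert_allclose(fwd - bwd, net, atol=1e-12)


def test_exchange_zero_bound_gives_unidirectional(ecoli):
    net = ff.sample_net_fluxes(ecoli.network, 10, seed=3)
    exch = ff.assign_exchange(ecoli.network, net, exch_bound=0.0, seed=4)
    assert np.all(exch == 0.0)


def test_negative_exchange_bound_rejected(ecoli):
    with pytest.raises(SamplingError):
        ff.assign_exchange(ecoli.network, np.zeros(39), -1.0, seed=0)


def test_stratified_cohort_uniform_histogram(ecoli):
    rd = ecoli.ratio("glycolysis_vs_ppp")
    coh = ff.stratified_cohort(ecoli.network, rd, 10, 100, 1.0, seed=6)
    y = coh.ratios[rd.name]
    counts, _ = np.histogram(y, bins=10, range=(0, 1))
    assert len(coh) == 1000
    # every decile within 5% of the nominal 100 per bin
    assert counts.min() >= 95 and counts.max() <= 105


def test_stratified_cohort_reports_infeasible_bins(ecoli):
    rd = ecoli.ratio("oaa_from_glyoxylate")  # structurally capped at 0.5
    with pytest.warns(UserWarning, match="infeasible"):
        coh = ff.stratified_cohort(ecoli.network, rd, 10, 20, 1.0, seed=6)
    lows = [lo for lo, hi in coh.metadata["infeasible_bins"]]
    assert 0.9 in [pytest.approx(x) for x in lows]
    assert coh.ratios[rd.name].max() <= 0.5 + 1e-9


def test_single_path_ratio_fixed_at_one():
    """Chain network: the 'ratio' along the only path is identically 1."""
    net = ff.toy_chain()
    rd = RatioDefinition("all", [RatioTerm("r2")], [RatioTerm("r2")])
    with pytest.warns(UserWarning, match="infeasible"):
        coh = ff.stratified_cohort(net, rd, 10, 5, 0.0, seed=0)
    assert np.allclose(coh.ratios["all"], 1.0)
    assert len(coh.metadata["infeasible_bins"]) == 9


def test_flux_state_validation(ecoli):
    s = ff.sample_net_fluxes(ecoli.network, 3, seed=11)
    exch = ff.assign_exchange(ecoli.network, s, 1.0, seed=12)
    for i in range(3):
        ff.FluxState(ecoli.network, s[i], exch[i]).validate()
    bad = ff.FluxState(ecoli.network, s[0], -exch[0] - 1.0)
    with pytest.raises(SamplingError):
        bad.validate()


def test_multi_ratio_cohort_labels_all_ratios(bsubtilis):
    rds = [bsubtilis.ratio("glycolysis_vs_ppp"), bsubtilis.ratio("oaa_from_pyr")]
    coh = ff.multi_ratio_cohort(bsubtilis.network, rds, 5, 20, 1.0, seed=2)
    assert set(coh.ratios) == {"glycolysis_vs_ppp", "oaa_from_pyr"}
    assert len(coh) == sum(
        (5 - len(v)) * 20 for v in coh.metadata["infeasible_bins"].values()
    )
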