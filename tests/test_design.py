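import numpy as np
import pytest
from scipy import stats

import fluxforest as ff
from fluxforest.errors import PredictorError


# ---------------------------------------------------------------------------
# IQR diagnostic

def test_identical_samples_show_no_shift():
    w = np.linspace(0.1, 0.3, 50)
    assert ff.iqr_diagnostic(w, w) == pytest.approx(0.5, abs=0.05)


def test_clear_shift_detected():
    rng = np.random.default_rng(0)
    b = rng.uniform(0.1, 0.3, 50)
    a = b + 0.2
    p = ff.iqr_diagnostic(a, b)
    # closed-form check: all 50 a's exceed all 50 b's -> U statistic maximal
    expect = stats.mannwhitneyu(a, b, alternative="greater").pvalue
    assert p == pytest.approx(expect)
    assert p < 0.01
    # and the reverse direction is not significant
    assert ff.iqr_diagnostic(b, a) > 0.99


def test_quantile_arrays_accepted():
    rng = np.random.default_rng(1)
    qa = np.column_stack([np.zeros(30), rng.uniform(0.3, 0.4, 30)])
    qb = np.column_stack([np.zeros(30), rng.uniform(0.1, 0.2, 30)])
    assert ff.iqr_diagnostic(qa, qb) < 0.01


def test_small_samples_refused():
    with pytest.raises(PredictorError, match="at least 3"):
        ff.iqr_diagnostic([0.1, 0.2], [0.1, 0.2, 0.3])


def test_exact_method_for_small_samples():
    a = [0.5, 0.6, 0.7, 0.8]
    b = [0.1, 0.2, 0.3, 0.4]
    p = ff.iqr_diagnostic(a, b)
    # exact one-sided rank-sum p for complete separation of 4 vs 4
    assert p == pytest.approx(1 / 70, rel=1e-6)


# ---------------------------------------------------------------------------
# design scan plumbing (tiny grid on the two-source fixture)

@pytest.fixture(scope="module")
def two_source_cohort():
    fx = ff.make_two_source_fixture()
    coh = ff.stratified_cohort(fx.network, fx.ratio_defs[0], 5, 120, 1.0, seed=3)
    return fx, coh


def test_single_cell_grid_equals_direct_run(two_source_cohort):
    fx, coh = two_source_cohort
    grid = ff.scan_designs(
        fx.network, coh, {"t": fx.tracer}, {"p": fx.spec}, fx.ratio_defs,
        seed=4, noise_level=0.01, feature_selection=False, n_bins=5,
    )
    assert len(grid.table) == 1
    assert not grid.failures
    mae = grid.mae("t", "p", "frac_a")
    assert 0 <= mae < 0.05
    assert grid.pivot("frac_a").shape == (1, 1)


def test_scan_records_failures_and_continues(two_source_cohort):
    fx, coh = two_source_cohort
    from fluxforest.measurements import Fragment, MeasurementSpec

    bad_spec = MeasurementSpec(
        [Fragment("nope", "does_not_exist", (1,))], platform="lcms"
    )
    grid = ff.scan_designs(
        fx.network, coh, {"t": fx.tracer},
        {"bad": bad_spec, "good": fx.spec},
        fx.ratio_defs, seed=4, noise_level=0.01, feature_selection=False,
        n_bins=5,
    )
    assert len(grid.table) == 1  # good cell survived
    assert len(grid.failures) == 1
    assert grid.failures[0]["platform"] == "bad"


def test_sensitivity_grid_structure(two_source_cohort):
    fx, _ = two_source_cohort
    res = ff.sensitivity_grid(
        fx.network, fx.ratio_defs,
        noise_levels=(0.0, 0.05), exch_bounds=(1.0,),
        seed=5, tracer=fx.tracer, spec=fx.spec,
        cohort_per_bin=120, n_bins=5,
        components=("matched", "noise_mismatch"),
    )
    r = res["frac_a"]
    assert len(r["matched"]) == 2
    nm = r["noise_mismatch"]
    assert len(nm) == 4
    piv = nm.pivot(index="train_noise", columns="test_noise", values="mae")
    # training on clean data, testing on noisy data hurts
    assert piv.loc[0.0, 0.05] > piv.loc[0.05, 0.05] - 0.005
    # MAE is non-decreasing in test noise for a fixed predictor
    assert piv.loc[0.0, 0.05] >= piv.loc[0.0, 0.0] - 0.005
    assert piv.loc[0.05, 0.05] >= piv.loc[0.05, 0.0] - 0.005
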