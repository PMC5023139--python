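import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluxforest as ff
from fluxforest.errors import MeasurementError
from fluxforest.measurements import Fragment, MeasurementSpec


@pytest.fixture
def spec3():
    return MeasurementSpec(
        [Fragment("m_123", "m", (1, 2, 3)), Fragment("m_23", "m", (2, 3))],
        platform="lcms",
    )


def test_fragment_position_validation():
    with pytest.raises(MeasurementError, match="increasing"):
        Fragment("x", "m", (2, 1))
    with pytest.raises(MeasurementError, match="empty"):
        Fragment("x", "m", ())
    with pytest.raises(MeasurementError, match="1-based"):
        Fragment("x", "m", (0, 1))
    assert Fragment("x", "m", (1, 3)).atoms == (0, 2)


def test_extract_feature_count_and_order(spec3):
    mdvs = {
        ("m", (0, 1, 2)): np.array([[0.5, 0.3, 0.1, 0.1]]),
        ("m", (1, 2)): np.array([[0.6, 0.3, 0.1]]),
    }
    X = ff.extract_features(mdvs, spec3)
    assert X.shape == (1, 7)  # (3+1) + (2+1) features
    assert spec3.manifest[0] == "m_123.M+0"
    np.testing.assert_allclose(X[0, :4], [0.5, 0.3, 0.1, 0.1])


def test_extract_missing_fragment_names_it(spec3):
    with pytest.raises(MeasurementError, match="m_23"):
        ff.extract_features({("m", (0, 1, 2)): np.zeros((1, 4))}, spec3)


def test_empty_spec_rejected():
    spec = MeasurementSpec([], platform="lcms")
    with pytest.raises(MeasurementError, match="no fragments"):
        ff.extract_features({}, spec)


def test_gcms_feature_count_is_block_sum(ecoli):
    spec = ecoli.spec("gcms")
    assert len(spec.fragments) == 21
    assert spec.n_features == sum(f.n_carbons + 1 for f in spec.fragments)
    assert len(spec.manifest) == spec.n_features


def test_zero_noise_is_identity(spec3):
    X = np.array([[0.5, 0.3, 0.1, 0.1, 0.6, 0.3, 0.1]])
    np.testing.assert_array_equal(ff.add_noise(X, 0.0, 0, spec3), X)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.001, 0.2), st.integers(0, 1000))
def test_noised_blocks_renormalize_and_stay_nonnegative(eps, seed):
    spec = MeasurementSpec(
        [Fragment("m_123", "m", (1, 2, 3)), Fragment("m_23", "m", (2, 3))],
        platform="lcms",
    )
    X = np.tile([0.5, 0.3, 0.1, 0.1, 0.6, 0.3, 0.1], (20, 1))
    Xn = ff.add_noise(X, eps, seed, spec)
    assert np.all(Xn >= 0)
    for start, stop in spec.blocks:
        np.testing.assert_allclose(Xn[:, start:stop].sum(axis=1), 1.0, atol=1e-12)


def test_noise_bound_before_normalization(spec3):
    """Perturbations are uniform on [-eps, eps]: bounded and seed-stable."""
    X = np.tile([0.5, 0.3, 0.1, 0.1, 0.6, 0.3, 0.1], (10000, 1))
    eps = 0.01
    rng = np.random.default_rng(77)
    raw = X + rng.uniform(-eps, eps, size=X.shape)
    assert np.abs(raw - X).max() <= eps
    a = ff.add_noise(X[:5], eps, 42, spec3)
    b = ff.add_noise(X[:5], eps, 42, spec3)
    np.testing.assert_array_equal(a, b)


def test_noise_is_unbiased_for_small_eps(spec3):
    X = np.tile([0.5, 0.3, 0.1, 0.1, 0.6, 0.3, 0.1], (20000, 1))
    Xn = ff.add_noise(X, 0.05, 3, spec3)
    np.testing.assert_allclose(Xn.mean(axis=0), X[0], atol=5e-3)


def test_read_mdv_table_roundtrip(spec3):
    rows = ["fragment\tmass\tfraction\tsample"]
    vals = {"m_123": [0.5, 0.3, 0.1, 0.1], "m_23": [0.6, 0.3, 0.1]}
    for frag, fracs in vals.items():
        for k, v in enumerate(fracs):
            rows.append(f"{frag}\t{k}\t{v}\ts1")
    X = ff.read_mdv_table(io.StringIO("\n".join(rows)), spec3)
    np.testing.assert_allclose(X, [[0.5, 0.3, 0.1, 0.1, 0.6, 0.3, 0.1]])


def test_read_mdv_table_missing_entry_rejected(spec3):
    table = "fragment\tmass\tfraction\nm_123\t0\t1.0\n"
    with pytest.raises(MeasurementError, match="missing"):
        ff.read_mdv_table(io.StringIO(table), spec3)
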