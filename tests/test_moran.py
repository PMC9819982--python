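import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smoglink as sl
from smoglink.moran import MoranError

from conftest import random_weights


def moran_double_loop(x, W):
    """Literal double-loop evaluation of the global statistic."""
    n = len(x)
    xbar = x.mean()
    s2 = ((x - xbar) ** 2).sum() / n
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += W[i, j]
    return num / (s2 * s0)


def local_double_loop(x, W):
    n = len(x)
    xbar = x.mean()
    s2 = ((x - xbar) ** 2).sum() / n
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += W[i, j] * (x[j] - xbar)
        out[i] = (x[i] - xbar) * acc / s2
    return out


def test_checkerboard_four_cycle_is_minus_one(ring4):
    x = np.array([1.0, -1.0, 1.0, -1.0])
    res = sl.global_moran(x, ring4)
    assert res.I == pytest.approx(-1.0, abs=1e-12)
    np.testing.assert_allclose(sl.local_moran(x, ring4), -1.0, atol=1e-12)


def test_expected_value_closed_form(ring4):
    res = sl.global_moran(np.array([3.0, 1.0, 4.0, 1.5]), ring4)
    assert res.expected_I == pytest.approx(-1.0 / 3.0)
    # n = 30 closed form
    assert -1.0 / 29.0 == pytest.approx(-0.03448, abs=5e-6)


def test_global_and_local_match_double_loop_oracle():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(5, 15))
        w = random_weights(rng, n)
        if rng.random() < 0.5:
            w = sl.row_standardize(w)
        x = rng.standard_normal(n)
        assert sl.global_moran(x, w).I == pytest.approx(moran_double_loop(x, w.w), abs=1e-12)
        np.testing.assert_allclose(sl.local_moran(x, w), local_double_loop(x, w.w), atol=1e-12)


def test_mean_of_local_equals_global_for_row_standardized(ring12):
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.standard_normal(12)
        assert sl.local_moran(x, ring12).mean() == pytest.approx(
            sl.global_moran(x, ring12).I, abs=1e-10
        )


def test_region_at_mean_has_zero_local(ring4):
    x = np.array([2.0, 1.0, 0.0, 1.0])  # region B and D exactly at the mean
    local = sl.local_moran(x, ring4)
    assert local[1] == pytest.approx(0.0, abs=1e-14)


@settings(deadline=None, max_examples=50)
@given(
    st.floats(min_value=-5, max_value=5).filter(lambda a: abs(a) > 1e-3),
    st.floats(min_value=-10, max_value=10),
    st.integers(min_value=0, max_value=1000),
)
def test_scale_and_shift_invariance(a, c, seed):
    """I(a x + c) = I(x) for a != 0."""
    rng = np.random.default_rng(seed)
    w = sl.row_standardize(random_weights(rng, 10))
    x = rng.standard_normal(10)
    assert sl.global_moran(a * x + c, w).I == pytest.approx(sl.global_moran(x, w).I, abs=1e-9)


def test_constant_vector_and_small_n_errors(ring4):
    with pytest.raises(MoranError, match="constant"):
        sl.global_moran(np.ones(4), ring4)
    w2 = sl.SpatialWeights(w=np.array([[0.0, 1.0], [1.0, 0.0]]), region_ids=("A", "B"))
    with pytest.raises(MoranError, match="n >= 3"):
        sl.global_moran(np.array([1.0, 2.0]), w2)


def test_permutation_clustered_blocks_significant():
    rng = np.random.default_rng(2)
    ids = [f"R{i:02d}" for i in range(20)]
    ring = sl.row_standardize(sl.build_contiguity(sl.ring_adjacency(20, ids), ids))
    x = np.concatenate([np.full(10, 5.0), np.zeros(10)]) + 0.01 * rng.standard_normal(20)
    res = sl.permutation_test(x, ring, n_perm=999, seed=0)
    assert res.p_perm <= 0.01


def test_permutation_deterministic(ring12):
    x = np.random.default_rng(3).standard_normal(12)
    a = sl.permutation_test(x, ring12, n_perm=199, seed=9)
    b = sl.permutation_test(x, ring12, n_perm=199, seed=9)
    assert a.p_perm == b.p_perm


def test_permutation_type_one_error_calibrated(ring12):
    """Pure-noise x: rejection at alpha=0.05 lands near nominal."""
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        x = rng.standard_normal(12)
        res = sl.permutation_test(x, ring12, n_perm=199, seed=rng)
        rejections += res.p_perm <= 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_permutation_null_mean_matches_expectation(ring12):
    """E[I] under the permutation null is -1/(n-1) within Monte-Carlo error."""
    rng = np.random.default_rng(29)
    x = rng.standard_normal(12)
    n_perm = 9999
    idx = np.argsort(rng.random((n_perm, 12)), axis=1)
    z = x - x.mean()
    Z = z[idx].T
    W = ring12.w
    I_perm = 12 * np.einsum("ip,ip->p", Z, W @ Z) / (W.sum() * (z @ z))
    se = I_perm.std() / np.sqrt(n_perm)
    assert abs(I_perm.mean() - (-1.0 / 11.0)) <= 3 * se


def test_quadrants_two_block(ring12):
    x = np.concatenate([np.full(6, 5.0), np.zeros(6)])
    labels = sl.moran_quadrants(x, ring12)
    # interior block members sit with like-valued neighbours
    assert set(labels) <= {"HH", "LL", "HL", "LH"}
    assert labels[2] == "HH" and labels[8] == "LL"


def test_quadrants_checkerboard(ring4):
    labels = sl.moran_quadrants(np.array([1.0, -1.0, 1.0, -1.0]), ring4)
    assert set(labels) == {"HL", "LH"}


def test_moran_with_locals_bundles_everything(ring12):
    x = np.random.default_rng(4).standard_normal(12)
    res = sl.moran_with_locals(x, ring12, n_perm=199, seed=1)
    assert res.local_I is not None and len(res.local_I) == 12
    assert res.quadrant is not None and len(res.quadrant) == 12
    assert res.p_perm is not None
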