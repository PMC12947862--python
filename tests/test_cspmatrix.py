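"""CSP² contact matrices: outer products, smoothing, composites and
difference maps."""

import numpy as np
import pytest

from idrmap.csp import CSPProfile
from idrmap.cspmatrix import (
    CSPSquaredMatrix,
    ReciprocalTitration,
    argmax_position,
    assemble_composite,
    build_pair_matrix,
    difference_matrix,
    smooth_matrix,
)


def profile(values, construct="A", start=1):
    return CSPProfile(construct, start, np.asarray(values, dtype=float))


def test_hand_outer_product():
    pair = ReciprocalTitration(profile([1.0, 2.0], "A"),
                               profile([3.0, 4.0, 5.0], "B"))
    m = build_pair_matrix(pair)
    assert np.array_equal(m.values, [[3.0, 4.0, 5.0], [6.0, 8.0, 10.0]])


def test_zero_profiles_give_zero_matrix():
    pair = ReciprocalTitration(profile([0.0, 0.0], "A"),
                               profile([0.0, 0.0, 0.0], "B"))
    assert not build_pair_matrix(pair).values.any()


def test_outer_product_oracle_with_missing(rng):
    for _ in range(20):
        a = rng.uniform(0, 0.1, 15)
        b = rng.uniform(0, 0.1, 12)
        a[rng.integers(0, 15, 3)] = np.nan
        b[rng.integers(0, 12, 2)] = np.nan
        m = build_pair_matrix(
            ReciprocalTitration(profile(a, "A"), profile(b, "B")))
        for i in range(15):
            for j in range(12):
                expected = a[i] * b[j]
                if np.isnan(expected):
                    assert np.isnan(m.values[i, j])
                else:
                    assert m.values[i, j] == pytest.approx(expected)


def test_fully_defined_matrix_is_rank_one(rng):
    a, b = rng.uniform(0.01, 0.1, 10), rng.uniform(0.01, 0.1, 8)
    m = build_pair_matrix(
        ReciprocalTitration(profile(a, "A"), profile(b, "B")))
    assert np.linalg.matrix_rank(m.values, tol=1e-10) == 1


def test_self_pair_diagonal_is_squared_csp():
    p = profile([0.1, 0.2, 0.3], "A")
    m = build_pair_matrix(ReciprocalTitration(p, p))
    assert np.allclose(np.diag(m.values), np.array([0.1, 0.2, 0.3]) ** 2)
    assert np.allclose(m.values, m.values.T)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def test_smooth_constant_unchanged():
    m = CSPSquaredMatrix("A", 1, "B", 1, np.full((9, 9), 2.5))
    for sigma in (0.5, 2.0, 4.0):
        assert np.allclose(smooth_matrix(m, sigma).values, 2.5)


def test_smooth_single_spike_matches_closed_form_kernel():
    n = 41
    v = np.zeros((n, n))
    v[20, 20] = 1.0
    sm = smooth_matrix(CSPSquaredMatrix("A", 1, "B", 1, v), sigma=2.0).values
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    kernel = np.exp(-((ii - 20) ** 2 + (jj - 20) ** 2) / (2 * 2.0 ** 2))
    kernel /= kernel.sum()
    # interior: denominator (weight field) is ~1, so result = kernel
    assert np.allclose(sm[5:-5, 5:-5], kernel[5:-5, 5:-5], atol=1e-8)


def test_smooth_fills_missing_with_neighbourhood_value():
    v = np.full((7, 7), 4.0)
    v[3, 3] = np.nan
    sm = smooth_matrix(CSPSquaredMatrix("A", 1, "B", 1, v), sigma=1.5).values
    assert sm[3, 3] == pytest.approx(4.0)


def test_smooth_preserves_nonnegativity_and_max(rng):
    v = rng.uniform(0, 1, (20, 20))
    v[rng.integers(0, 20, 10), rng.integers(0, 20, 10)] = np.nan
    sm = smooth_matrix(CSPSquaredMatrix("A", 1, "B", 1, v), sigma=2.0).values
    finite = sm[np.isfinite(sm)]
    assert (finite >= 0).all()
    assert finite.max() <= np.nanmax(v) + 1e-12


def test_smooth_all_missing_raises():
    m = CSPSquaredMatrix("A", 1, "B", 1, np.full((4, 4), np.nan))
    with pytest.raises(ValueError):
        smooth_matrix(m)


# ---------------------------------------------------------------------------
# composite assembly
# ---------------------------------------------------------------------------


def test_single_self_pair_composite_equals_block():
    p = profile([0.1, 0.2, 0.3], "A", start=1)
    block = build_pair_matrix(ReciprocalTitration(p, p))
    comp = assemble_composite([ReciprocalTitration(p, p)], full_length=3)
    assert np.allclose(comp.values, block.values, equal_nan=True)


def test_disjoint_blocks_leave_missing_elsewhere():
    a = profile([0.1, 0.2], "A", start=1)
    b = profile([0.3, 0.4], "B", start=5)
    comp = assemble_composite([ReciprocalTitration(a, b)], full_length=6,
                              mirror=False)
    assert np.isfinite(comp.values[0:2, 4:6]).all()
    assert np.isnan(comp.values[0:2, 0:2]).all()


def test_mirrored_composite_is_symmetric():
    a = profile([0.1, 0.2], "A", start=1)
    b = profile([0.3, 0.4, 0.5], "B", start=4)
    comp = assemble_composite([ReciprocalTitration(a, b)], full_length=6)
    assert np.allclose(comp.values, comp.values.T, equal_nan=True)


def test_overlap_mean_rule():
    p1 = profile([2.0, 2.0], "A", start=1)
    p2 = profile([4.0, 4.0], "A", start=1)
    comp = assemble_composite(
        [ReciprocalTitration(p1, p1), ReciprocalTitration(p2, p2)],
        full_length=2, overlap_rule="mean")
    # cell values: mean of 4 and 16
    assert np.allclose(comp.values, 10.0)
    comp_max = assemble_composite(
        [ReciprocalTitration(p1, p1), ReciprocalTitration(p2, p2)],
        full_length=2, overlap_rule="max")
    assert np.allclose(comp_max.values, 16.0)


def test_overlap_without_rule_raises():
    p = profile([1.0, 1.0], "A", start=1)
    with pytest.raises(ValueError, match="overlap"):
        assemble_composite(
            [ReciprocalTitration(p, p), ReciprocalTitration(p, p)],
            full_length=2, overlap_rule=None)


# ---------------------------------------------------------------------------
# difference maps
# ---------------------------------------------------------------------------


def matrix(values):
    return CSPSquaredMatrix("A", 1, "B", 1, np.asarray(values, dtype=float))


def test_difference_arithmetic_and_masking():
    holo = matrix([[5.0, 5.0, np.nan]])
    apo = matrix([[2.0, 0.0, 2.0]])
    d = difference_matrix(holo, apo)
    assert d.values[0, 0] == 3.0     # both defined, both nonzero
    assert d.values[0, 1] == 0.0     # apo zero -> masked
    assert d.values[0, 2] == 0.0     # holo missing -> masked
    assert d.masked_count == 2


def test_difference_masking_count_matches_brute_force(rng):
    for _ in range(20):
        h = rng.uniform(0, 1, (10, 10))
        a = rng.uniform(0, 1, (10, 10))
        h[rng.random((10, 10)) < 0.2] = np.nan
        a[rng.random((10, 10)) < 0.2] = 0.0
        d = difference_matrix(matrix(h), matrix(a))
        brute = sum(
            1 for i in range(10) for j in range(10)
            if np.isnan(h[i, j]) or np.isnan(a[i, j])
            or h[i, j] == 0 or a[i, j] == 0
        )
        assert d.masked_count == brute
        # masked positions are exactly zero
        n_zero = int((d.values == 0).sum())
        assert n_zero >= brute


def test_difference_coordinate_mismatch_raises():
    with pytest.raises(ValueError):
        difference_matrix(matrix([[1.0]]), matrix([[1.0, 2.0]]))


def test_argmax_position_in_construct_coordinates():
    m = CSPSquaredMatrix("A", 10, "B", 100,
                         np.array([[0.0, 1.0], [0.5, 0.2]]))
    assert argmax_position(m) == (10, 101)
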