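import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeglm import (
    KnotGrid,
    boundary_weights_first,
    boundary_weights_last,
    build_basis_matrix,
    hermite_components,
    interior_weights,
    single_segment_weights,
)
from conftest import random_knot_grid

finite_u = st.floats(min_value=0.0, max_value=1.0)
tensions = st.floats(min_value=0.05, max_value=2.0)
ratios = st.floats(min_value=1.1, max_value=5.0)


# ---------------------------------------------------------------- hermite


def test_hermite_endpoints():
    assert hermite_components(0.0) == (1.0, 0.0, 0.0, 0.0)
    assert hermite_components(1.0) == (0.0, 0.0, 1.0, 0.0)


def test_hermite_midpoint():
    h00, h10, h01, h11 = hermite_components(0.5)
    assert np.allclose([h00, h10, h01, h11], [0.5, 0.125, 0.5, -0.125])


@pytest.mark.parametrize("u", [-0.1, 1.1, np.nan])
def test_hermite_domain_error(u):
    with pytest.raises(ValueError):
        hermite_components(u)


# ---------------------------------------------------------------- segment weights


def test_interior_weights_at_zero():
    w = interior_weights(0.0, 0.7, 1.9, 2.4)
    assert np.allclose(w, [0.0, 1.0, 0.0, 0.0])


def test_interior_weights_midpoint_uniform():
    w = interior_weights(0.5, 0.5, 2.0, 2.0)
    assert np.allclose(w, [-0.125, 0.625, 0.625, -0.125])


def test_boundary_first_examples():
    assert np.allclose(boundary_weights_first(0.0, 0.5, 2.0), [1, 0, 0])
    assert np.allclose(boundary_weights_first(1.0, 0.5, 2.0), [0, 1, 0])
    assert np.allclose(boundary_weights_first(0.5, 0.5, 2.0), [0.625, 0.5, -0.125])


def test_boundary_last_examples():
    assert np.allclose(boundary_weights_last(1.0, 0.5, 2.0), [0, 0, 1])
    assert np.allclose(boundary_weights_last(0.0, 0.5, 2.0), [0, 1, 0])
    assert np.allclose(boundary_weights_last(0.5, 0.5, 2.0), [-0.125, 0.5, 0.625])


def test_single_segment_examples():
    assert np.allclose(single_segment_weights(0.0), [1, 0])
    assert np.allclose(single_segment_weights(0.5), [0.5, 0.5])
    assert np.allclose(single_segment_weights(1.0), [0, 1])


@given(u=finite_u, s=tensions, l1=ratios, l2=ratios)
def test_interior_partition_of_unity(u, s, l1, l2):
    assert abs(interior_weights(u, s, l1, l2).sum() - 1.0) < 1e-12


@given(u=finite_u, s=tensions, lb=ratios)
def test_boundary_partition_of_unity(u, s, lb):
    assert abs(boundary_weights_first(u, s, lb).sum() - 1.0) < 1e-12
    assert abs(boundary_weights_last(u, s, lb).sum() - 1.0) < 1e-12
    assert abs(single_segment_weights(u).sum() - 1.0) < 1e-12


def test_interior_weights_nonfinite_error():
    with pytest.raises(ValueError):
        interior_weights(0.5, np.nan, 2.0, 2.0)


# ---------------------------------------------------------------- linear-solve oracle

_HERMITE_SYSTEM = np.array(
    [
        [0.0, 0.0, 0.0, 1.0],  # S(0)
        [1.0, 1.0, 1.0, 1.0],  # S(1)
        [0.0, 0.0, 1.0, 0.0],  # S'(0)
        [3.0, 2.0, 1.0, 0.0],  # S'(1)
    ]
)


def _cubic_from_conditions(u, s0, s1, d0, d1):
    """Independent oracle: solve for the cubic satisfying the endpoint
    value/derivative conditions and evaluate it at u."""
    coef = np.linalg.solve(_HERMITE_SYSTEM, [s0, s1, d0, d1])
    return coef @ [u**3, u**2, u, 1.0]


def _oracle_interior(u, s, l1, l2):
    out = []
    for k in range(4):
        p = np.zeros(4)
        p[k] = 1.0
        out.append(
            _cubic_from_conditions(
                u, p[1], p[2], s * l1 * (p[2] - p[0]), s * l2 * (p[3] - p[1])
            )
        )
    return np.asarray(out)


def _oracle_first(u, s, lb):
    out = []
    for k in range(3):
        p = np.zeros(3)
        p[k] = 1.0
        out.append(_cubic_from_conditions(u, p[0], p[1], 0.0, s * lb * (p[2] - p[0])))
    return np.asarray(out)


def _oracle_last(u, s, le):
    out = []
    for k in range(3):
        p = np.zeros(3)
        p[k] = 1.0
        out.append(_cubic_from_conditions(u, p[1], p[2], s * le * (p[2] - p[0]), 0.0))
    return np.asarray(out)


@given(u=finite_u, s=tensions, l1=ratios, l2=ratios)
@settings(max_examples=50)
def test_interior_matches_linear_solve_oracle(u, s, l1, l2):
    np.testing.assert_allclose(
        interior_weights(u, s, l1, l2), _oracle_interior(u, s, l1, l2), atol=1e-12
    )


@given(u=finite_u, s=tensions, lb=ratios)
@settings(max_examples=50)
def test_boundaries_match_linear_solve_oracle(u, s, lb):
    np.testing.assert_allclose(
        boundary_weights_first(u, s, lb), _oracle_first(u, s, lb), atol=1e-12
    )
    np.testing.assert_allclose(
        boundary_weights_last(u, s, lb), _oracle_last(u, s, lb), atol=1e-12
    )


@given(u=finite_u)
def test_single_segment_matches_oracle(u):
    expected = [
        _cubic_from_conditions(u, 1.0, 0.0, 0.0, 0.0),
        _cubic_from_conditions(u, 0.0, 1.0, 0.0, 0.0),
    ]
    np.testing.assert_allclose(single_segment_weights(u), expected, atol=1e-12)


# ---------------------------------------------------------------- KnotGrid


def test_knot_grid_validation():
    with pytest.raises(ValueError):
        KnotGrid((0.0, 0.0, 1.0))
    with pytest.raises(ValueError):
        KnotGrid((0.0,), variant="modified")
    with pytest.raises(ValueError):
        KnotGrid((0.0, 1.0, 2.0), variant="cardinal")  # needs >= 4
    with pytest.raises(ValueError):
        KnotGrid((0.0, 1.0), tension=0.0)
    with pytest.raises(ValueError):
        KnotGrid((0.0, 1.0), variant="bogus")


def test_ghost_placement():
    g = KnotGrid.cardinal_with_ghosts((0.0, 10.0, 30.0), tension=0.5)
    assert g.locations == (-10.0, 0.0, 10.0, 30.0, 50.0)
    assert g.evaluable_range == (0.0, 30.0)


def test_dimension_modified_vs_cardinal():
    knots = (1.0, 10.0, 40.0, 100.0, 200.0)
    m = KnotGrid(knots, variant="modified").evaluate([1.0, 50.0, 200.0])
    c = KnotGrid.cardinal_with_ghosts(knots).evaluate([1.0, 50.0, 200.0])
    assert m.n_basis == 5
    assert c.n_basis == 7


# ---------------------------------------------------------------- basis matrix


def test_interpolation_one_hot_modified():
    grid = KnotGrid((0.0, 1.0, 3.0, 7.0), tension=0.8)
    basis = grid.evaluate(np.asarray(grid.locations))
    np.testing.assert_allclose(basis.matrix, np.eye(4), atol=1e-12)


def test_interpolation_one_hot_cardinal_interior():
    grid = KnotGrid.cardinal_with_ghosts((0.0, 1.0, 3.0, 7.0), tension=0.8)
    basis = grid.evaluate(np.asarray(grid.locations[1:-1]))
    expected = np.zeros((4, 6))
    expected[np.arange(4), np.arange(1, 5)] = 1.0
    np.testing.assert_allclose(basis.matrix, expected, atol=1e-12)


@pytest.mark.parametrize("variant,n_knots", [("modified", 2), ("modified", 3),
                                             ("modified", 6), ("cardinal", 6)])
def test_partition_of_unity_random_grids(variant, n_knots):
    rng = np.random.default_rng(42)
    for _ in range(20):
        grid = random_knot_grid(rng, n_knots, variant)
        lo, hi = grid.evaluable_range
        values = rng.uniform(lo, hi, size=50)
        basis = grid.evaluate(values)
        np.testing.assert_allclose(basis.matrix.sum(axis=1), 1.0, atol=1e-12)


def _spline_fn(grid, p):
    return lambda x: grid.evaluate(np.atleast_1d(x)).matrix @ p


@pytest.mark.parametrize("variant,n_knots", [("modified", 5), ("cardinal", 7)])
def test_c0_c1_continuity_at_interior_knots(variant, n_knots):
    # C1 holds exactly only for uniform spacing: the printed spacing-ratio
    # convention makes the knot derivative segment-local otherwise
    rng = np.random.default_rng(7)
    grid = random_knot_grid(rng, n_knots, variant, uniform=True)
    p = rng.normal(size=n_knots)
    f = _spline_fn(grid, p)
    loc = np.asarray(grid.locations)
    lo, hi = grid.evaluable_range
    interior = loc[(loc > lo) & (loc < hi)]
    spacing = np.min(np.diff(loc))
    h = 1e-4 * spacing  # third-order stencil: truncation ~h^3, round-off ~eps/h
    for xk in interior:
        d_right = (
            -11 * f(xk) + 18 * f(xk + h) - 9 * f(xk + 2 * h) + 2 * f(xk + 3 * h)
        ) / (6 * h)
        d_left = (
            11 * f(xk) - 18 * f(xk - h) + 9 * f(xk - 2 * h) - 2 * f(xk - 3 * h)
        ) / (6 * h)
        assert abs(f(xk + 1e-12) - f(xk - 1e-12)) < 1e-10  # C0
        assert abs(d_right - d_left) < 1e-10 * max(np.max(np.abs(p)) / spacing, 1.0)


def test_flat_boundary_derivative_modified():
    rng = np.random.default_rng(11)
    for n_knots in (2, 3, 5):
        grid = random_knot_grid(rng, n_knots, "modified")
        p = rng.normal(size=n_knots)
        f = _spline_fn(grid, p)
        loc = np.asarray(grid.locations)
        spacing = np.min(np.diff(loc))
        h = 1e-6 * spacing
        scale = max(np.max(np.abs(p)) / spacing, 1.0)
        d0 = (-3 * f(loc[0]) + 4 * f(loc[0] + h) - f(loc[0] + 2 * h)) / (2 * h)
        d1 = (3 * f(loc[-1]) - 4 * f(loc[-1] - h) + f(loc[-1] - 2 * h)) / (2 * h)
        assert abs(d0) < 1e-8 * scale
        assert abs(d1) < 1e-8 * scale


def test_out_of_range_raises_with_context():
    grid = KnotGrid((0.0, 1.0, 2.0))
    with pytest.raises(ValueError, match="2.5"):
        grid.evaluate([0.5, 2.5])


def test_out_of_range_clamp_logs(caplog):
    grid = KnotGrid((0.0, 1.0, 2.0))
    with caplog.at_level("WARNING", logger="spikeglm.splines"):
        basis = grid.evaluate([-0.5, 0.5, 2.5], out_of_range="clamp")
    assert "clamped 2" in caplog.text
    np.testing.assert_allclose(basis.matrix[0], [1, 0, 0], atol=1e-12)
    np.testing.assert_allclose(basis.matrix[2], [0, 0, 1], atol=1e-12)


def test_half_open_segment_convention():
    # value at an interior knot belongs to the right-hand segment; the
    # maximum belongs to the last segment — both still interpolate exactly
    grid = KnotGrid((0.0, 1.0, 2.0, 3.0))
    basis = build_basis_matrix([1.0, 3.0], grid)
    np.testing.assert_allclose(basis.matrix[0], [0, 1, 0, 0], atol=1e-12)
    np.testing.assert_allclose(basis.matrix[1], [0, 0, 0, 1], atol=1e-12)


def test_two_knot_grid_basis():
    grid = KnotGrid((0.0, 4.0))
    basis = grid.evaluate([0.0, 2.0, 4.0])
    np.testing.assert_allclose(
        basis.matrix, [[1, 0], [0.5, 0.5], [0, 1]], atol=1e-12
    )
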