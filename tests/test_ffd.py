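"""Bernstein FFD algebra and the inverse least-squares solve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ffdreg.errors import OutOfSupportError
from ffdreg.ffd import (
    FFDGrid,
    bernstein_row,
    build_deformation_matrix,
    displacement_jacobian,
    forward_deform,
    init_grid,
    interpolate_displacement,
    inverse_solve,
    local_coords,
)


@pytest.fixture(scope="module")
def grid555():
    return init_grid([0, 0, 0], [63, 63, 63], 5, 5, 5, margin=0.0)


class TestGrid:
    def test_unit_cube_degree_one_has_corner_controls(self):
        g = init_grid([0, 0, 0], [1, 1, 1], 1, 1, 1, margin=0.0)
        assert g.n_controls == 8
        corners = {tuple(p) for p in g.rest_points()}
        assert corners == {(x, y, z) for x in (0.0, 1.0) for y in (0.0, 1.0)
                           for z in (0.0, 1.0)}

    def test_margin_inflates_extent_per_axis(self):
        g = init_grid([0, 0, 0], [10, 10, 10], 1, 1, 1, margin=0.1)
        np.testing.assert_allclose(g.S, [12, 0, 0])
        np.testing.assert_allclose(g.x0, [-1, -1, -1])

    def test_five_cubed_grid_has_216_controls(self, grid555):
        assert grid555.n_controls == 216

    def test_degenerate_axes_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            FFDGrid([0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 1], 2, 2, 2)

    def test_grid_round_trips_through_json(self, tmp_path, grid555):
        grid555.to_json(tmp_path / "grid.json")
        back = FFDGrid.from_json(tmp_path / "grid.json")
        np.testing.assert_allclose(back.P, grid555.P)
        assert (back.l, back.m, back.n) == (5, 5, 5)


class TestLocalCoords:
    def test_origin_and_far_corner(self, grid555):
        np.testing.assert_allclose(local_coords(grid555, grid555.x0), [0, 0, 0],
                                   atol=1e-12)
        far = grid555.x0 + grid555.S + grid555.T + grid555.U
        np.testing.assert_allclose(local_coords(grid555, far), [1, 1, 1], atol=1e-12)

    def test_sheared_grid_matches_direct_linear_solve(self):
        g = FFDGrid([1, 2, 3], [10, 1, 0], [2, 8, 1], [0, 3, 12], 2, 2, 2)
        rng = np.random.default_rng(0)
        M = np.column_stack([g.S, g.T, g.U])
        for _ in range(20):
            x = g.x0 + M @ rng.uniform(0, 1, 3)
            expected = np.linalg.solve(M, x - g.x0)
            np.testing.assert_allclose(local_coords(g, x), expected, atol=1e-10)


class TestBernsteinRows:
    def test_corner_point_gets_unit_weight(self, grid555):
        row = bernstein_row(grid555, grid555.x0)
        assert row[grid555.flat_index(0, 0, 0)] == pytest.approx(1.0)
        assert np.count_nonzero(row > 1e-12) == 1

    def test_degree_one_center_weights_are_one_eighth(self):
        g = init_grid([0, 0, 0], [1, 1, 1], 1, 1, 1, margin=0.0)
        np.testing.assert_allclose(bernstein_row(g, [0.5, 0.5, 0.5]), np.full(8, 0.125))

    def test_linear_precision_reproduces_points(self, grid555):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0.5, 62.5, size=(1000, 3))
        B = build_deformation_matrix(grid555, pts)
        np.testing.assert_allclose(B.B.sum(axis=1), 1.0, atol=1e-12)
        err = np.abs(B.B @ grid555.rest_points() - pts)
        assert err.max() < 1e-9
        assert B.B.min() >= 0 and B.B.max() <= 1
        assert B.shape == (1000, 216)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3))
    def test_partition_of_unity_everywhere_inside(self, xyz):
        g = init_grid([0, 0, 0], [1, 1, 1], 3, 2, 4, margin=0.0)
        row = bernstein_row(g, np.asarray(xyz))
        assert abs(row.sum() - 1.0) < 1e-12

    def test_point_outside_support_rejected(self, grid555):
        with pytest.raises(OutOfSupportError) as err:
            build_deformation_matrix(grid555, np.array([[1.0, 1.0, 1.0], [-5, 1, 1]]))
        assert list(err.value.offenders) == [1]

    def test_affine_map_of_controls_is_reproduced(self, grid555):
        # linear precision: an affine map applied to the control points acts
        # exactly as the same affine map on every interior point
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3)) * 0.2 + np.eye(3)
        b = rng.normal(size=3)
        pts = rng.uniform(1, 62, size=(200, 3))
        B = build_deformation_matrix(grid555, pts)
        moved = forward_deform(B, grid555.rest_points() @ A.T + b)
        np.testing.assert_allclose(moved, pts @ A.T + b, atol=1e-9)


class TestForwardDeform:
    def test_rest_controls_are_the_identity(self, grid555):
        rng = np.random.default_rng(3)
        pts = rng.uniform(1, 62, size=(50, 3))
        B = build_deformation_matrix(grid555, pts)
        np.testing.assert_allclose(forward_deform(B, grid555.rest_points()), pts,
                                   atol=1e-10)

    def test_uniform_translation_translates_every_point(self, grid555):
        rng = np.random.default_rng(4)
        pts = rng.uniform(1, 62, size=(50, 3))
        t = np.array([2.0, -1.0, 0.5])
        B = build_deformation_matrix(grid555, pts)
        np.testing.assert_allclose(forward_deform(B, grid555.rest_points() + t),
                                   pts + t, atol=1e-10)

    def test_matches_per_point_row_evaluation(self, grid555):
        rng = np.random.default_rng(5)
        pts = rng.uniform(1, 62, size=(20, 3))
        P_star = grid555.rest_points() + rng.normal(size=(216, 3))
        B = build_deformation_matrix(grid555, pts)
        stacked = forward_deform(B, P_star)
        for i, x in enumerate(pts):
            np.testing.assert_allclose(stacked[i], bernstein_row(grid555, x) @ P_star,
                                       atol=1e-12)

    def test_shape_mismatch_rejected(self, grid555):
        B = build_deformation_matrix(grid555, np.full((5, 3), 10.0))
        with pytest.raises(ValueError):
            forward_deform(B, np.zeros((8, 3)))


@pytest.fixture(scope="module")
def instance(grid555):
    rng = np.random.default_rng(6)
    pts = rng.uniform(1, 62, size=(5000, 3))
    B = build_deformation_matrix(grid555, pts)
    cell = 63.0 / 5.0
    P_true = grid555.rest_points() + rng.uniform(-0.2, 0.2, (216, 3)) * cell
    return B, P_true, forward_deform(B, P_true)


class TestInverseSolve:
    def test_pinv_recovers_known_controls(self, grid555, instance):
        B, P_true, S = instance
        sol = inverse_solve(B, S, P_rest=grid555.rest_points(), method="pinv", lam=0.0)
        assert np.sqrt(np.mean((sol.P_star - P_true) ** 2)) < 1e-6

    def test_lm_agrees_with_pinv_when_well_conditioned(self, grid555, instance):
        B, P_true, S = instance
        p1 = inverse_solve(B, S, P_rest=grid555.rest_points(), method="pinv", lam=0.0)
        p2 = inverse_solve(B, S, P_rest=grid555.rest_points(), method="lm", lam=1e-12)
        assert p2.converged
        assert np.sqrt(np.mean((p1.P_star - p2.P_star) ** 2)) < 1e-4

    def test_rest_targets_return_rest_controls_under_ridge(self, grid555):
        rng = np.random.default_rng(7)
        pts = rng.uniform(1, 62, size=(2000, 3))
        B = build_deformation_matrix(grid555, pts)
        sol = inverse_solve(B, pts, P_rest=grid555.rest_points(), method="pinv")
        np.testing.assert_allclose(sol.P_star, grid555.rest_points(), atol=1e-6)

    def test_rank_deficient_system_warns_and_returns_min_norm(self, grid555):
        rng = np.random.default_rng(8)
        pts = rng.uniform(30, 33, size=(50, 3))  # too few, too clustered
        B = build_deformation_matrix(grid555, pts)
        with pytest.warns(UserWarning):
            sol = inverse_solve(B, pts, method="pinv", lam=0.0)
        assert sol.residual_rms < 1e-8  # still fits the data

    def test_residual_is_reported_in_mm(self, grid555, instance):
        B, P_true, S = instance
        rng = np.random.default_rng(9)
        noisy = S + rng.normal(0, 0.1, S.shape)
        sol = inverse_solve(B, noisy, P_rest=grid555.rest_points(), method="pinv",
                            lam=0.0)
        assert 0.05 < sol.residual_rms < 0.3


class TestInterpolation:
    def test_rest_and_translation_cases(self, grid555):
        rng = np.random.default_rng(10)
        x = rng.uniform(1, 62, size=(20, 3))
        np.testing.assert_allclose(
            interpolate_displacement(grid555, grid555.rest_points(), x), x, atol=1e-10)
        t = np.array([3.0, 1.0, -2.0])
        np.testing.assert_allclose(
            interpolate_displacement(grid555, grid555.rest_points() + t, x), x + t,
            atol=1e-10)

    def test_jacobian_matches_finite_differences(self, grid555):
        rng = np.random.default_rng(11)
        P_star = grid555.rest_points() + rng.normal(0, 2.0, (216, 3))
        x = rng.uniform(5, 58, size=(5, 3))
        J = displacement_jacobian(grid555, P_star, x)
        h = 1e-5
        for p in range(len(x)):
            for ax in range(3):
                step = np.zeros(3)
                step[ax] = h
                fd = (interpolate_displacement(grid555, P_star, x[p] + step)
                      - interpolate_displacement(grid555, P_star, x[p] - step)) / (2 * h)
                np.testing.assert_allclose(J[p, :, ax], fd, atol=1e-6)
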