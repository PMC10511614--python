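"""Shape functions, inverse bilinear mapping, homogeneous re-mesh and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aaastrain import MotionGrid, build_averaged_model, make_homogeneous_grid
from aaastrain.averaging import (
    UnwrappedSurface,
    acquisition_axis,
    average_models,
    inverse_bilinear,
    shape_functions,
    shape_function_derivatives,
    track_homogeneous_points,
)
from aaastrain.core import Axis

from conftest import cylinder_grid


class TestShapeFunctions:
    def test_centroid_gives_equal_weights(self):
        np.testing.assert_array_equal(shape_functions(0, 0), [0.25] * 4)

    @pytest.mark.parametrize("corner,expected", [
        ((-1, -1), [1, 0, 0, 0]),
        ((1, -1), [0, 1, 0, 0]),
        ((1, 1), [0, 0, 1, 0]),
        ((-1, 1), [0, 0, 0, 1]),
    ])
    def test_nodal_interpolation_property(self, corner, expected):
        np.testing.assert_array_equal(shape_functions(*corner), expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_partition_of_unity(self, r, s):
        # analytically exact; floating point leaves at most one ulp
        assert abs(shape_functions(r, s).sum() - 1.0) <= 1e-15

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_derivatives_sum_to_zero(self, r, s):
        np.testing.assert_allclose(
            shape_function_derivatives(r, s).sum(axis=-1), 0.0, atol=1e-15
        )


class TestInverseBilinear:
    def test_rectangle_closed_form(self):
        # axis-aligned rectangle: the inverse map is affine and known exactly
        quad = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float)
        rs = inverse_bilinear(quad, np.array([0.5, 0.25]))
        np.testing.assert_allclose(rs, [-0.5, -0.5], atol=1e-9)

    def test_centroid_maps_to_origin(self):
        quad = np.array([[0, 0], [3, 0.5], [3.5, 2], [-0.5, 1.5]])
        rs = inverse_bilinear(quad, quad.mean(axis=0))
        np.testing.assert_allclose(rs, [0, 0], atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_forward_map_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        base = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        quad = base + rng.uniform(-0.2, 0.2, size=(4, 2))
        rs_true = rng.uniform(-0.99, 0.99, size=2)
        p = shape_functions(*rs_true) @ quad
        rs = inverse_bilinear(quad, p)
        assert rs is not None
        forward = shape_functions(*rs) @ quad
        np.testing.assert_allclose(forward, p, atol=1e-9)


class TestReferenceSurface:
    def test_perfect_cylinder_radius_constant(self):
        grid = cylinder_grid(radius=10.0, n=8)
        axis = acquisition_axis([grid])
        surf = UnwrappedSurface(grid, axis)
        lo, hi = surf.axial_range
        for f in (0.05, 0.37, 0.93):
            for phi in (-3.0, -1.0, 0.4, 2.9):
                R, pos = surf(lo + f * (hi - lo), phi)
                assert np.isclose(R, 10.0, atol=1e-9)
                assert np.isclose(np.hypot(pos[0], pos[1]), 10.0, atol=1e-9)

    def test_interpolation_reproduces_nodes(self):
        grid = cylinder_grid(radius=12.0, n=6)
        axis = acquisition_axis([grid])
        surf = UnwrappedSurface(grid, axis)
        from aaastrain.core import to_cylindrical

        cyl = to_cylindrical(grid.nodes(0), axis)
        for k in (37, 95, 140):
            R, pos = surf(cyl.x_long[k], cyl.phi[k])
            np.testing.assert_allclose(pos, grid.nodes(0)[k], atol=1e-8)

    def test_cone_midpoint_is_mean_of_ring_radii(self):
        # radius linear in x: bilinear interpolation is exact on linear fields
        n, m = 5, 36
        x = np.linspace(0, 40, n)
        phi = 2 * np.pi * np.arange(m) / m - np.pi
        X, PHI = np.meshgrid(x, phi, indexing="ij")
        R = 8.0 + 0.1 * X
        pos = np.stack([R * np.cos(PHI), R * np.sin(PHI), X], axis=-1)
        grid = MotionGrid(np.stack([pos, pos]))
        axis = Axis(pos.reshape(-1, 3).mean(axis=0), [0, 0, 1])
        surf = UnwrappedSurface(grid, axis)
        from aaastrain.core import to_cylindrical

        cyl = to_cylindrical(grid.nodes(0), axis)
        xl = cyl.x_long.reshape(n, m)
        x_mid = 0.5 * (xl[1, 3] + xl[2, 3])
        R_mid, _ = surf(x_mid, cyl.phi[3])
        expected = 0.5 * ((8.0 + 0.1 * x[1]) + (8.0 + 0.1 * x[2]))
        assert np.isclose(R_mid, expected, atol=1e-9)

    def test_query_outside_axial_range_raises(self):
        grid = cylinder_grid(n=5, length=40.0)
        surf = UnwrappedSurface(grid, acquisition_axis([grid]))
        with pytest.raises(ValueError, match="axial range"):
            surf(1000.0, 0.0)

    def test_fold_over_detected_with_height_pair(self):
        grid = cylinder_grid(n=5, length=40.0)
        pos = grid.positions.copy()
        pos[:, [1, 2]] = pos[:, [2, 1]]  # swap two rings axially
        bad = MotionGrid(pos)
        with pytest.raises(ValueError, match="heights 1 and 2"):
            UnwrappedSurface(bad, acquisition_axis([grid]))


class TestHomogeneousGrid:
    def test_identical_segmentations_have_coinciding_anchors(self):
        grid = cylinder_grid(n=8)
        hg = make_homogeneous_grid([grid, grid, grid], n_H=6)
        np.testing.assert_allclose(hg.ref_positions[0], hg.ref_positions[1], atol=1e-9)
        np.testing.assert_allclose(hg.ref_positions[0], hg.ref_positions[2], atol=1e-9)

    def test_coaxial_cylinders_keep_their_radii(self):
        g10 = cylinder_grid(radius=10.0, n=8)
        g12 = cylinder_grid(radius=12.0, n=6)
        hg = make_homogeneous_grid([g10, g12], n_H=5)
        r0 = np.linalg.norm(hg.ref_positions[0][:, :2], axis=1)
        r1 = np.linalg.norm(hg.ref_positions[1][:, :2], axis=1)
        np.testing.assert_allclose(r0, 10.0, atol=1e-6)
        np.testing.assert_allclose(r1, 12.0, atol=1e-6)

    def test_target_count(self):
        grid = cylinder_grid(n=12)
        hg = make_homogeneous_grid([grid, grid], n_H=10, m_H=36)
        assert hg.ref_positions.shape[1] == 360

    def test_anchor_local_coordinates_within_element(self):
        grid = cylinder_grid(n=8)
        hg = make_homogeneous_grid([grid, grid], n_H=6)
        assert np.all(np.abs(hg.anchors.rs) <= 1 + 1e-6)

    def test_empty_axial_overlap_rejected(self):
        a = cylinder_grid(n=6, length=50.0)
        b = cylinder_grid(n=6, length=50.0)
        b.positions[..., 2] += 100.0
        with pytest.raises(ValueError, match="overlap"):
            make_homogeneous_grid([a, b])


class TestTracking:
    def test_rigid_translation_moves_points_identically(self):
        grid = cylinder_grid(n=6, frames=(1.0, 1.0))
        d = np.array([1.0, -2.0, 0.5])
        grid.positions[1] += d
        hg = make_homogeneous_grid([grid], n_H=5)
        traj = track_homogeneous_points(hg, 0)
        np.testing.assert_allclose(traj[1] - traj[0], np.broadcast_to(d, traj[0].shape), atol=1e-9)

    def test_uniform_inflation_scales_about_axis(self):
        grid = cylinder_grid(radius=10.0, n=6, frames=(1.0, 1.05))
        hg = make_homogeneous_grid([grid], n_H=5)
        traj = track_homogeneous_points(hg, 0)
        r0 = np.linalg.norm(traj[0][:, :2], axis=1)
        r1 = np.linalg.norm(traj[1][:, :2], axis=1)
        np.testing.assert_allclose(r1 / r0, 1.05, atol=1e-9)

    def test_corner_anchor_follows_node_trajectory(self):
        rng = np.random.default_rng(0)
        grid = cylinder_grid(n=6)
        grid.positions[1] += rng.normal(0, 0.1, size=grid.positions[1].shape)
        hg = make_homogeneous_grid([grid], n_H=5)
        # move one anchor onto a host-element corner and retrack
        hg.anchors.rs[0, 7] = (-1.0, -1.0)
        traj = track_homogeneous_points(hg, 0)
        e = hg.anchors.element[0, 7]
        node = hg.surfaces[0].mesh.elements[e][0]
        for t in range(grid.n_frames):
            np.testing.assert_allclose(traj[t, 7], grid.nodes(t)[node], atol=1e-12)


class TestAveraging:
    def test_mean_of_identical_inputs_is_any_input(self):
        tr = np.random.default_rng(0).normal(size=(3, 2, 10, 3))
        one = tr[0]
        out = average_models([one, one.copy(), one.copy()][:3])
        np.testing.assert_allclose(out, one, rtol=1e-15, atol=1e-15)

    def test_two_trajectories_average_to_midpoint(self):
        p = np.random.default_rng(1).normal(size=(2, 5, 3))
        d = np.array([1.0, 2.0, 3.0])
        out = average_models([p, p + d])
        np.testing.assert_allclose(out, p + d / 2, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        a = np.zeros((2, 5, 3))
        b = np.zeros((2, 6, 3))
        with pytest.raises(ValueError, match="mismatch"):
            average_models([a, b])

    def test_points_stay_inside_host_element_hull(self, default_truth):
        # convex elements: tracked homogeneous points remain convex combos
        from aaastrain import make_segmentations

        segs = make_segmentations(default_truth, K=2, seed=11)
        hg = make_homogeneous_grid(segs)
        traj = track_homogeneous_points(hg, 0)
        elems = hg.anchors.element[0]
        nodes = hg.surfaces[0].mesh.elements[elems]
        for t in (0, segs[0].n_frames // 2):
            pts = segs[0].nodes(t)[nodes]  # (P, 4, 3)
            lo = pts.min(axis=1) - 1e-9
            hi = pts.max(axis=1) + 1e-9
            assert np.all(traj[t] >= lo) and np.all(traj[t] <= hi)

    def test_averaged_model_reduces_node_noise(self, default_truth):
        from aaastrain import make_segmentations
        from aaastrain.phantom import radial_residual

        spec = default_truth.spec
        w = spec.waveform(np.arange(spec.n_frames))
        errs = {}
        for K in (1, 6):
            segs = make_segmentations(default_truth, K=K, seed=21)
            model, hg = build_averaged_model(segs)
            res = [radial_residual(spec, model.grid.nodes(t), w[t]) for t in range(spec.n_frames)]
            errs[K] = np.sqrt(np.mean(np.square(res)))
        assert errs[6] < 0.6 * errs[1]
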