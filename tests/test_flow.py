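"""Eshelby inclusion fields, the FEM flow solver and the velocity residual."""

import numpy as np
import pytest

from germorder.eshelby import (InclusionSpec, foci_displacements,
                               inclusion_displacement, interior_strain)
from germorder.flow import (FlowField, annulus_mesh, average_division_flow,
                            division_only_prediction, fit_inclusion_params,
                            punctured_rectangle_mesh, solve_navier,
                            solve_tissue_flow, velocity_residual)

NU = 1.0 / 3.0


def _ring_points(r, n=32):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestInclusionField:
    def test_zero_amplitudes_zero_field(self):
        spec = InclusionSpec(center=(0, 0), radius=1.0, M=0.0, q=0.0)
        u = inclusion_displacement(_ring_points(3.0), spec, NU)
        assert np.allclose(u, 0.0)

    def test_interior_point_rejected(self):
        spec = InclusionSpec(center=(0, 0), radius=1.0, M=0.5)
        with pytest.raises(ValueError, match="inside"):
            inclusion_displacement(np.array([[0.2, 0.1]]), spec, NU)

    def test_rotational_equivariance(self):
        pts = _ring_points(2.5, 17)
        phi = 0.9
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        s1 = InclusionSpec(center=(0, 0), radius=1.0, M=0.4, q=0.3, axis=0.2)
        s2 = InclusionSpec(center=(0, 0), radius=1.0, M=0.4, q=0.3, axis=0.2 + phi)
        u1 = inclusion_displacement(pts, s1, NU)
        u2 = inclusion_displacement(pts @ R.T, s2, NU)
        assert np.allclose(u2, u1 @ R.T, atol=1e-12)

    def test_linearity_in_amplitudes(self):
        pts = _ring_points(2.0, 11)
        base = dict(center=(0, 0), radius=1.0, axis=0.3)
        uM = inclusion_displacement(pts, InclusionSpec(M=1.0, **base), NU)
        uq = inclusion_displacement(pts, InclusionSpec(q=1.0, **base), NU)
        u = inclusion_displacement(pts, InclusionSpec(M=0.7, q=-0.4, **base), NU)
        assert np.allclose(u, 0.7 * uM - 0.4 * uq, atol=1e-12)

    def test_pure_dilatation_matches_axisymmetric_fd_oracle(self):
        # radial Navier ODE u'' + u'/r - u/r^2 = 0 solved by finite
        # differences on [a, R] with the matched boundary value at r = a
        import scipy.sparse as sp
        from scipy.sparse.linalg import spsolve

        a, M = 1.0, 0.7
        spec = InclusionSpec(center=(0, 0), radius=a, M=M, q=0.0)
        u_a = inclusion_displacement(np.array([[a, 0.0]]), spec, NU)[0, 0]
        R_far, n = 400.0, 60_000
        r = np.linspace(a, R_far, n)
        h = r[1] - r[0]
        rin = r[1:-1]
        A = sp.diags([(1 / h ** 2 - 1 / (2 * rin * h))[1:],
                      -2 / h ** 2 - 1 / rin ** 2,
                      (1 / h ** 2 + 1 / (2 * rin * h))[:-1]], [-1, 0, 1],
                     format="csc")
        rhs = np.zeros(n - 2)
        rhs[0] -= (1 / h ** 2 - 1 / (2 * rin[0] * h)) * u_a
        u_fd = spsolve(A, rhs)
        rr = np.linspace(1.5 * a, 10 * a, 18)
        u_ana = inclusion_displacement(
            np.column_stack([rr, np.zeros_like(rr)]), spec, NU)[:, 0]
        u_interp = np.interp(rr, rin, u_fd)
        assert np.all(np.abs(u_interp - u_ana) / np.abs(u_ana) < 0.01)

    def test_far_field_decay(self):
        spec = InclusionSpec(center=(0, 0), radius=1.0, M=0.5, q=0.3, axis=0.1)
        near = np.linalg.norm(inclusion_displacement(_ring_points(2.0), spec, NU), axis=1)
        far = np.linalg.norm(inclusion_displacement(_ring_points(200.0), spec, NU), axis=1)
        assert far.max() < 0.02 * near.max()

    def test_foci_lie_along_extensile_axis(self):
        spec = InclusionSpec(center=(0, 0), radius=1.0, M=0.2, q=0.3, axis=0.5)
        f = foci_displacements(spec, NU)
        assert np.allclose(f[0], -f[1])
        direction = f[0] / np.linalg.norm(f[0])
        assert abs(direction @ spec.n_hat) == pytest.approx(1.0, abs=1e-12)


class TestFemSolver:
    def test_no_inclusions_zero_boundary_gives_zero(self):
        f, _ = solve_tissue_flow((0, 0, 10, 8), [], np.zeros(2), mesh_size=1.0)
        assert np.abs(f.vectors).max() < 1e-10

    def test_constant_boundary_gives_constant_field(self):
        U = np.array([1.0, -2.0])
        f, _ = solve_tissue_flow((0, 0, 10, 8), [], U, mesh_size=1.0)
        assert np.allclose(f.vectors, U, atol=1e-10)

    def test_fem_matches_analytic_single_inclusion(self):
        spec = InclusionSpec(center=(0, 0), radius=1.0, M=0.6, q=0.3, axis=0.4)
        mesh = annulus_mesh(1.0, 12.0, n_rings=48)
        dirichlet = {}
        for ring, strict in ((mesh.exterior_nodes, True), (mesh.hole_nodes[0], False)):
            vals = inclusion_displacement(mesh.nodes[ring], spec, NU,
                                          strict_exterior=strict)
            dirichlet.update({int(i): tuple(v) for i, v in zip(ring, vals)})
        sol = solve_navier(mesh, dirichlet, NU)
        r = np.hypot(*mesh.nodes.T)
        band = (r >= 2.0) & (r <= 5.0)
        ana = inclusion_displacement(mesh.nodes[band], spec, NU)
        err = np.linalg.norm(sol[band] - ana) / np.linalg.norm(ana)
        assert err < 0.02

    def test_refinement_monotonically_reduces_error(self):
        spec = InclusionSpec(center=(0, 0), radius=1.0, M=0.5, q=0.2, axis=0.0)
        errs = []
        for rings in (12, 24, 48):
            mesh = annulus_mesh(1.0, 12.0, n_rings=rings)
            dirichlet = {}
            for ring, strict in ((mesh.exterior_nodes, True),
                                 (mesh.hole_nodes[0], False)):
                vals = inclusion_displacement(mesh.nodes[ring], spec, NU,
                                              strict_exterior=strict)
                dirichlet.update({int(i): tuple(v) for i, v in zip(ring, vals)})
            sol = solve_navier(mesh, dirichlet, NU)
            r = np.hypot(*mesh.nodes.T)
            band = (r >= 2.0) & (r <= 5.0)
            ana = inclusion_displacement(mesh.nodes[band], spec, NU)
            errs.append(np.linalg.norm(sol[band] - ana) / np.linalg.norm(ana))
        assert errs[0] > errs[1] > errs[2]

    def test_solution_linear_in_amplitudes_and_boundary_data(self):
        rect = (0, 0, 12, 10)
        base = dict(center=(6.0, 5.0), radius=1.0, axis=0.3)
        mesh = punctured_rectangle_mesh(rect, [(6.0, 5.0, 1.0)], h=0.6)

        def solve(M, q, U):
            specs = [InclusionSpec(M=M, q=q, **base)]
            f, _ = solve_tissue_flow(rect, specs, np.asarray(U), nu=NU, mesh=mesh)
            return f.vectors

        uM = solve(1.0, 0.0, [0, 0])
        uq = solve(0.0, 1.0, [0, 0])
        uU = solve(0.0, 0.0, [0.5, -0.2])
        combo = solve(0.8, -0.3, [0.5, -0.2])
        assert np.allclose(combo, 0.8 * uM - 0.3 * uq + uU, atol=1e-8)

    def test_hole_geometry_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            punctured_rectangle_mesh((0, 0, 10, 10),
                                     [(4, 5, 1.0), (5, 5, 1.0)])
        with pytest.raises(ValueError, match="exterior boundary"):
            punctured_rectangle_mesh((0, 0, 10, 10), [(0.5, 5, 1.0)])


class TestVelocityResidual:
    def test_identical_fields_zero(self):
        pts = np.random.default_rng(0).normal(size=(40, 2))
        u = FlowField(pts, np.random.default_rng(1).normal(size=(40, 2)))
        r = velocity_residual(u, u)
        assert np.allclose(r.residual, 0.0)

    def test_scale_invariance(self):
        pts = np.random.default_rng(0).normal(size=(40, 2))
        u = FlowField(pts, np.random.default_rng(1).normal(size=(40, 2)))
        v = FlowField(pts, 2.7 * u.vectors)
        assert np.allclose(velocity_residual(u, v).residual, 0.0, atol=1e-12)

    def test_orthogonal_typical_fields_give_one(self):
        th = np.random.default_rng(2).uniform(0, 2 * np.pi, 50)
        pts = np.random.default_rng(3).normal(size=(50, 2))
        u = FlowField(pts, np.column_stack([np.cos(th), np.sin(th)]))
        v = FlowField(pts, np.column_stack([-np.sin(th), np.cos(th)]))
        assert np.allclose(velocity_residual(u, v).residual, 1.0, atol=1e-12)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(60, 2))
        u = FlowField(pts, rng.normal(size=(60, 2)))
        v = FlowField(pts, rng.normal(size=(60, 2)))
        r_uv = velocity_residual(u, v)
        r_vu = velocity_residual(v, u)
        assert np.array_equal(r_uv.residual, r_vu.residual)
        assert np.all(r_uv.residual >= 0)

    def test_zero_field_rejected(self):
        pts = np.zeros((3, 2))
        u = FlowField(pts, np.zeros((3, 2)))
        v = FlowField(pts, np.ones((3, 2)))
        with pytest.raises(ValueError):
            velocity_residual(u, v)


class TestAmplitudeFit:
    def test_inverse_crime_recovery(self):
        rect = (0.0, 0.0, 20.0, 14.0)
        truth = [InclusionSpec(center=(8., 7.), radius=1.0, M=0.6, q=0.3, axis=0.3),
                 InclusionSpec(center=(14., 5.), radius=0.8, M=0.6, q=0.3, axis=-0.5)]
        adv = (0.2, 0.1)
        f, mesh = solve_tissue_flow(rect, truth, np.asarray(adv), advection=adv,
                                    nu=NU, mesh_size=0.5)
        from scipy.interpolate import LinearNDInterpolator
        rng = np.random.default_rng(2)
        pts = rng.uniform([0.5, 0.5], [19.5, 13.5], size=(250, 2))
        keep = np.ones(len(pts), bool)
        for s in truth:
            keep &= np.hypot(pts[:, 0] - s.center[0],
                             pts[:, 1] - s.center[1]) > s.radius + 0.3
        pts = pts[keep]
        v = LinearNDInterpolator(mesh.nodes, f.vectors)(pts)
        ok = np.isfinite(v[:, 0])
        measured = FlowField(pts[ok], v[ok], "measured")
        bare = [InclusionSpec(center=s.center, radius=s.radius, axis=s.axis)
                for s in truth]
        M, q, _ = fit_inclusion_params(measured, bare, rect, nu=NU, advection=adv,
                                       mesh_size=0.5, exterior_velocity=np.asarray(adv))
        assert M == pytest.approx(0.6, rel=0.05)
        assert q == pytest.approx(0.3, rel=0.05)

    def test_zero_measured_field_recovers_zero(self):
        rect = (0.0, 0.0, 12.0, 10.0)
        bare = [InclusionSpec(center=(6., 5.), radius=1.0, axis=0.2)]
        rng = np.random.default_rng(1)
        pts = rng.uniform([1, 1], [11, 9], size=(80, 2))
        pts = pts[np.hypot(pts[:, 0] - 6, pts[:, 1] - 5) > 1.5]
        v = np.zeros((len(pts), 2))
        M, q, _ = fit_inclusion_params(FlowField(pts, v), bare, rect, nu=NU,
                                       advection=(0, 0), mesh_size=0.7,
                                       exterior_velocity=np.zeros(2))
        assert abs(M) < 0.02 and abs(q) < 0.02

    def test_no_divisions_rejected(self):
        with pytest.raises(ValueError, match="homogeneous"):
            fit_inclusion_params(FlowField(np.zeros((3, 2)), np.ones((3, 2))),
                                 [], (0, 0, 1, 1))


class TestDivisionOnly:
    def test_empty_list_zero_field(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        f = division_only_prediction([], pts, NU)
        assert np.allclose(f.vectors, 0.0)

    def test_single_division_equals_inclusion_field(self):
        spec = InclusionSpec(center=(1., 2.), radius=0.5, M=0.4, q=0.2, axis=0.7)
        pts = np.array([[3.0, 2.0], [1.0, 4.0], [-1.0, 0.0]])
        f = division_only_prediction([spec], pts, NU)
        assert np.allclose(f.vectors, inclusion_displacement(pts, spec, NU))

    def test_well_separated_near_fields(self):
        s1 = InclusionSpec(center=(0., 0.), radius=1.0, M=0.5, q=0.2, axis=0.0)
        s2 = InclusionSpec(center=(60., 0.), radius=1.0, M=0.5, q=0.2, axis=0.0)
        pts = _ring_points(1.5, 16)  # near field of inclusion 1
        both = division_only_prediction([s1, s2], pts, NU)
        single = inclusion_displacement(pts, s1, NU)
        rel = np.linalg.norm(both.vectors - single) / np.linalg.norm(single)
        assert rel < 0.05


class TestAverageDivisionFlow:
    @staticmethod
    def _patch(axis, com=(0.0, 0.0), n=1500, seed=0, noise=0.0):
        spec = InclusionSpec(center=(0, 0), radius=0.5, M=0.4, q=0.3, axis=axis)
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-3, 3, size=(n, 2))
        pts = pts[np.hypot(*pts.T) > 0.6]
        vel = inclusion_displacement(pts, spec, NU)
        if noise:
            vel = vel + rng.normal(scale=noise, size=vel.shape)
        c, s = np.cos(axis - np.pi / 2), np.sin(axis - np.pi / 2)
        # nothing to rotate here: points/velocities are already lab-frame
        return {"points": pts + np.asarray(com), "velocities": vel,
                "com": np.asarray(com), "axis": axis}

    @staticmethod
    def _band(field, lo=0.8, hi=1.8):
        r = np.hypot(field.points[:, 0], field.points[:, 1])
        return (r > lo) & (r < hi)

    def test_single_patch_round_trip(self):
        p = self._patch(axis=np.pi / 2)
        avg = average_division_flow([p], grid_radius=2.0, grid_n=21)
        spec = InclusionSpec(center=(0, 0), radius=0.5, M=0.4, q=0.3, axis=np.pi / 2)
        band = self._band(avg)
        expect = inclusion_displacement(avg.points[band], spec, NU)
        err = np.linalg.norm(avg.vectors[band] - expect) / np.linalg.norm(expect)
        assert err < 0.05

    def test_rotated_patches_average_to_common_frame(self):
        # a patch whose division axis points elsewhere is co-rotated into
        # the axis-along-+y reference frame, so it averages consistently
        p1 = self._patch(axis=np.pi / 2, seed=1)
        p2 = self._patch(axis=0.9, seed=2)
        avg12 = average_division_flow([p1, p2], grid_radius=2.0, grid_n=21)
        spec = InclusionSpec(center=(0, 0), radius=0.5, M=0.4, q=0.3, axis=np.pi / 2)
        band = self._band(avg12)
        expect = inclusion_displacement(avg12.points[band], spec, NU)
        err = np.linalg.norm(avg12.vectors[band] - expect) / np.linalg.norm(expect)
        assert err < 0.05

    def test_noise_averages_out(self):
        spec = InclusionSpec(center=(0, 0), radius=0.5, M=0.4, q=0.3, axis=np.pi / 2)
        patches = [self._patch(axis=np.pi / 2, seed=s, noise=0.05)
                   for s in range(24)]
        avg = average_division_flow(patches, grid_radius=2.0, grid_n=21)
        band = self._band(avg)
        expect = inclusion_displacement(avg.points[band], spec, NU)
        err = np.linalg.norm(avg.vectors[band] - expect) / np.linalg.norm(expect)
        one = average_division_flow(patches[:1], grid_radius=2.0, grid_n=21)
        band1 = self._band(one)
        expect1 = inclusion_displacement(one.points[band1], spec, NU)
        err_one = np.linalg.norm(one.vectors[band1] - expect1) / np.linalg.norm(expect1)
        assert err < err_one

    def test_patch_without_com_skipped(self):
        p1 = self._patch(axis=np.pi / 2)
        p2 = dict(p1)
        p2["com"] = None
        with pytest.warns(UserWarning, match="skipped"):
            avg = average_division_flow([p1, p2], grid_radius=2.0, grid_n=15)
        assert len(avg.points) > 0
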