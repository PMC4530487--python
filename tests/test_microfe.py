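"""Micro-FE: element matrix, meshing, boundary conditions, solver."""

import numpy as np
import pytest

from bonefe.imageproc import BoneMask, SpanCrop, threshold_permille
from bonefe.microfe import (
    CORNER_OFFSETS,
    ConvergenceError,
    Material,
    assemble,
    build_model,
    export_mesh,
    hex8_element_matrix,
    read_vtk_mesh,
    solve,
    voxel_mesh,
)
from bonefe.phantoms import PhantomSpec, generate_femur_phantom

from conftest import bar_crop, make_bar_mask, make_bar_model


class TestElementMatrix:
    def test_symmetric_with_exactly_six_rigid_modes(self):
        ke = hex8_element_matrix(Material(), 50.0)
        np.testing.assert_allclose(ke, ke.T, atol=1e-12)
        w = np.linalg.eigvalsh(ke)
        assert np.sum(np.abs(w) < 1e-9 * w.max()) == 6
        assert w[6] > 1e-6 * w.max()  # remaining modes carry strain energy

    def test_rigid_translations_produce_no_force(self):
        ke = hex8_element_matrix(Material(), 50.0)
        for axis in range(3):
            t = np.zeros(24)
            t[axis::3] = 1.0
            assert np.abs(ke @ t).max() < 1e-10 * np.abs(ke).max()

    def test_linear_scaling_in_modulus_and_edge(self):
        base = hex8_element_matrix(Material(10.0, 0.3), 50.0)
        np.testing.assert_allclose(
            hex8_element_matrix(Material(20.0, 0.3), 50.0), 2 * base, rtol=1e-12
        )
        np.testing.assert_allclose(
            hex8_element_matrix(Material(10.0, 0.3), 100.0), 2 * base, rtol=1e-12
        )

    def test_uniaxial_strain_nodal_forces_match_elasticity_tensor(self):
        mat = Material(10.0, 0.3)
        h_um = 50.0
        h = h_um / 1000.0
        ke = hex8_element_matrix(mat, h_um)
        eps = 1e-3
        E, nu = mat.youngs_modulus_gpa * 1000.0, mat.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        sigma = np.array([(lam + 2 * mu) * eps, lam * eps, lam * eps])
        u = np.zeros(24)
        u[0::3] = CORNER_OFFSETS[:, 0] * h * eps  # u_x = eps * x
        f = ke @ u
        signs = 2 * CORNER_OFFSETS - 1
        expected = signs * sigma * h**2 / 4.0
        np.testing.assert_allclose(f.reshape(8, 3), expected, rtol=1e-10, atol=1e-12)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            Material(10.0, 0.5)
        with pytest.raises(ValueError):
            Material(-1.0, 0.3)


class TestMeshAndPatch:
    def test_node_count_equals_distinct_voxel_corners(self):
        rng = np.random.default_rng(0)
        grid = rng.random((4, 5, 6)) > 0.5
        grid[0, 0, 0] = True
        mask = BoneMask(grid, 50.0)
        elem_nodes, node_ijk, _ = voxel_mesh(mask)
        corners = set()
        for i, j, k in np.argwhere(grid):
            for oi, oj, ok in CORNER_OFFSETS:
                corners.add((i + oi, j + oj, k + ok))
        assert node_ijk.shape[0] == len(corners)
        assert elem_nodes.shape == (grid.sum(), 8)

    def test_affine_boundary_displacement_reproduces_constant_strain(self):
        """Mesh-level patch test: a fully meshed cuboid under affine Dirichlet
        data reproduces the affine field (hence constant strain) exactly."""
        mask = BoneMask(np.ones((3, 3, 3), dtype=bool), 50.0)
        elem_nodes, node_ijk, _ = voxel_mesh(mask)
        mat = Material()
        ke = hex8_element_matrix(mat, mask.voxel_size_um)
        n_nodes = node_ijk.shape[0]
        K = assemble(elem_nodes, ke, n_nodes).toarray()
        coords = node_ijk * mask.voxel_size_mm
        A = np.array([[2e-3, 1e-3, 0.0], [0.0, -1e-3, 5e-4], [1e-3, 0.0, 3e-3]])
        u_exact = coords @ A.T
        boundary = np.any((node_ijk == 0) | (node_ijk == 3), axis=1)
        fixed = np.repeat(np.flatnonzero(boundary), 3) * 3 + np.tile(
            [0, 1, 2], boundary.sum()
        )
        vals = u_exact[boundary].ravel()
        free = np.setdiff1d(np.arange(3 * n_nodes), fixed)
        u = np.zeros(3 * n_nodes)
        u[fixed] = vals
        u[free] = np.linalg.solve(K[np.ix_(free, free)], -K[np.ix_(free, fixed)] @ vals)
        err = np.abs(u.reshape(-1, 3) - u_exact).max()
        assert err <= 1e-10 * np.abs(u_exact).max()


class TestBoundaryConditions:
    def test_support_sets_lie_on_bottom_surface(self):
        spec = PhantomSpec(length_mm=2.0, outer_radius_mm=0.8,
                           cortical_thickness_mm=0.3, voxel_size_um=100.0)
        mask = threshold_permille(generate_femur_phantom(spec))
        crop = SpanCrop((0.3, 1.7))
        model = build_model(mask, Material(), crop)
        _, _, node_id = voxel_mesh(mask)
        exists = node_id >= 0
        kmin = np.argmax(exists, axis=2)
        for n in model.bc.support_nodes_a:
            i, j, k = model.node_ijk[n]
            assert k == kmin[i, j]
        kmax = exists.shape[2] - 1 - np.argmax(exists[:, :, ::-1], axis=2)
        for n in model.bc.load_nodes:
            i, j, k = model.node_ijk[n]
            assert k == kmax[i, j]

    def test_bone_missing_at_roller_is_geometry_error(self):
        grid = np.zeros((20, 3, 3), dtype=bool)
        grid[5:15] = True  # bone does not reach the roller planes
        mask = BoneMask(grid, 100.0)
        with pytest.raises(ValueError, match="roller"):
            build_model(mask, Material(), SpanCrop((0.1, 1.9)))

    def test_contact_band_width_acts_as_effective_span_change(self):
        """Widening the support band stiffens the model appreciably: the
        full-width vertical constraint over a finite band resists support
        rotation (documented BC sensitivity, not a small perturbation)."""
        mask = make_bar_mask(vox_um=100.0, n_len=24, n_side=4)
        k = {}
        for hw in (0, 1, 2):
            model = make_bar_model(mask, contact_halfwidth_vox=hw)
            k[hw] = solve(model).fe_stiffness_n_per_mm
        assert k[0] < k[1] < k[2]
        # the effect is large on a short span, not a small perturbation
        assert k[1] / k[0] > 1.05


class TestSolver:
    def test_doubling_modulus_doubles_stiffness(self, bar_mask):
        k1 = solve(make_bar_model(bar_mask, Material(10.0))).fe_stiffness_n_per_mm
        k2 = solve(make_bar_model(bar_mask, Material(20.0))).fe_stiffness_n_per_mm
        assert k2 == pytest.approx(2 * k1, rel=1e-9)

    def test_stiffness_independent_of_prescribed_displacement(self, bar_mask):
        m1 = make_bar_model(bar_mask, prescribed_displacement_mm=-0.01)
        m2 = make_bar_model(bar_mask, prescribed_displacement_mm=-0.02)
        k1 = solve(m1).fe_stiffness_n_per_mm
        k2 = solve(m2).fe_stiffness_n_per_mm
        assert k1 == pytest.approx(k2, rel=1e-8)

    def test_global_equilibrium(self, bar_model):
        sol = solve(bar_model, tol=1e-8)
        scale = abs(sol.reaction_force_n)
        assert abs(sol.reaction_force_n + sol.support_reaction_n) <= 1e-7 * scale

    def test_matfree_and_dense_agree(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            grid = np.ones((10, 3, 3), dtype=bool)
            cand = np.argwhere(grid[2:-2, :, 1:])  # keep contact faces intact
            drop = cand[rng.choice(len(cand), size=5, replace=False)]
            grid[drop[:, 0] + 2, drop[:, 1], drop[:, 2] + 1] = False
            mask = BoneMask(grid, 100.0)
            model = build_model(mask, Material(), bar_crop(mask))
            k_dense = solve(model, method="dense").fe_stiffness_n_per_mm
            k_free = solve(model, method="matfree", tol=1e-12).fe_stiffness_n_per_mm
            assert k_free == pytest.approx(k_dense, rel=1e-8)

    def test_removing_material_never_stiffens(self, bar_mask):
        k_full = solve(make_bar_model(bar_mask), method="dense").fe_stiffness_n_per_mm
        grid = bar_mask.grid.copy()
        grid[6, 1, 1] = False  # interior voxel away from contacts
        k_holed = solve(
            make_bar_model(BoneMask(grid, bar_mask.voxel_size_um)), method="dense"
        ).fe_stiffness_n_per_mm
        assert k_holed <= k_full * (1 + 1e-10)

    def test_nonconvergence_raises_with_history(self, bar_model):
        with pytest.raises(ConvergenceError) as exc:
            solve(bar_model, tol=1e-14, max_iter=3, method="cg")
        assert len(exc.value.residual_history) == 3

    def test_deterministic_solution(self, bar_model):
        s1 = solve(bar_model, method="cg")
        s2 = solve(bar_model, method="cg")
        assert s1.fe_stiffness_n_per_mm == s2.fe_stiffness_n_per_mm
        np.testing.assert_array_equal(s1.displacements, s2.displacements)


class TestExport:
    def test_vtk_roundtrip(self, tmp_path, bar_model):
        sol = solve(bar_model)
        path = tmp_path / "mesh.vtk"
        export_mesh(bar_model, sol, path)
        pts, cells, disp, reac = read_vtk_mesh(path)
        np.testing.assert_allclose(pts, bar_model.node_coords_mm(), rtol=1e-8)
        assert cells.shape[0] == bar_model.n_elements
        assert np.abs(disp).max() == pytest.approx(
            np.abs(sol.displacements).max(), rel=1e-6
        )
        # vertical reactions at supports balance the load-node reactions
        assert reac.sum() == pytest.approx(0.0, abs=1e-6 * abs(sol.reaction_force_n))
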