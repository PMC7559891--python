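import numpy as np
import pytest

from poroscaf import fem, geometry
from poroscaf.fem import (
    ConfigurationError,
    FEMResult,
    LoadCase,
    MaterialProperties,
    apparent_modulus,
    apply_load_case,
    base_reaction,
    build_column_model,
    build_fe_model,
    darcy_velocities,
    default_materials,
    element_strains,
    solve_consolidation,
    terzaghi_pressure,
)
from poroscaf.geometry import LabeledGrid, ScaffoldSpec

LUC = 0.637


class TestMaterialProperties:
    def test_table_defaults(self):
        mats = default_materials()
        gran, scaf = mats["granulation"], mats["scaffold"]
        assert gran.E == 0.2 and gran.nu == 0.167 and gran.porosity == 0.8
        assert gran.K_grain == 2300 and gran.K_fluid == 2300
        assert scaf.E == 1000 and scaf.nu == 0.3 and scaf.porosity == 0.5
        assert scaf.K_grain == 13920 and scaf.K_fluid == 2300
        # permeability 1e-14 m^4/(N s) -> 1e-2 mm^4/(N s)
        assert gran.k == pytest.approx(1e-2)
        assert scaf.k == pytest.approx(1e-2)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(E=-1),
            dict(nu=0.5),
            dict(nu=0.55),
            dict(k=0),
            dict(porosity=0.0),
            dict(porosity=1.0),
            dict(K_grain=-5),
        ],
    )
    def test_invalid_constants_rejected(self, kw):
        base = dict(E=1.0, nu=0.3, k=1e-2, porosity=0.5, K_grain=100.0, K_fluid=100.0)
        base.update(kw)
        with pytest.raises(ValueError):
            MaterialProperties(**base)

    def test_biot_coefficient_definition(self):
        m = MaterialProperties(E=1000, nu=0.3, k=1e-2, porosity=0.5,
                               K_grain=13920, K_fluid=2300)
        Kd = 1000 / (3 * (1 - 0.6))
        assert m.biot_alpha == pytest.approx(1 - Kd / 13920)
        assert m.storage == pytest.approx(0.5 / 2300 + (m.biot_alpha - 0.5) / 13920)


class TestLoadCase:
    def test_total_force_formula(self):
        load = LoadCase(mode="compression", F_UA=0.1)
        assert load.total_force(2.548) == pytest.approx(0.1 * 2.548**2)
        assert load.total_force(2.548) == pytest.approx(0.6492, abs=2e-4)

    def test_published_shear_magnitudes_accepted(self):
        for f in (0.01, 0.05, 0.1, 0.2, 0.5):
            LoadCase(mode="shear", F_UA=f)

    def test_zero_load_gives_zero_force_vector(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials,
                               LoadCase(mode="compression", F_UA=0.0))
        assert np.allclose(model.plate_force, 0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            LoadCase(mode="torsion", F_UA=0.1)

    def test_ramp_schedule(self):
        load = LoadCase(F_UA=0.1, ramp_time=1.0, n_increments=4)
        sched = load.schedule()
        assert [round(x, 10) for x, _ in sched] == [0.25, 0.5, 0.75, 1.0]
        assert [lam for _, lam in sched] == [0.25, 0.5, 0.75, 1.0]


class TestBuildModel:
    def test_node_and_dof_counts(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials, LoadCase())
        assert model.n_nodes == 9**3
        assert model.n_dofs == 4 * 9**3

    def test_base_nodes_all_encastred(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials, LoadCase())
        base = np.nonzero(model.node_coords[:, 2] == 0)[0]
        fixed = set(model.fixed_u_dofs.tolist())
        for n in base:
            for c in range(3):
                assert 3 * n + c in fixed

    def test_drained_faces_granulation_only(self, tiny_grid, materials):
        """Audit: every drained node lies on a lateral/bottom boundary face of
        at least one granulation element; purely scaffold-faced boundary nodes
        carry no drainage."""
        model = build_fe_model(tiny_grid, materials, LoadCase())
        labels = tiny_grid.labels
        n = labels.shape[0]
        h = model.h
        coords = model.node_coords
        gran_nodes = set()
        for e in range(model.n_elements):
            if model.elem_mat[e] != 0:  # granulation is material 0
                continue
            for node in model.elem_nodes[e]:
                gran_nodes.add(int(node))
        L = model.L
        for node in model.drained_nodes:
            x, y, z = coords[node]
            on_boundary = (
                np.isclose(x, 0) or np.isclose(x, L) or np.isclose(y, 0)
                or np.isclose(y, L) or np.isclose(z, 0)
            )
            assert on_boundary
            assert int(node) in gran_nodes

    def test_top_face_never_drained(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials, LoadCase())
        z = model.node_coords[model.drained_nodes, 2]
        assert np.all(z < model.L)

    def test_single_material_grid_rejected(self, materials):
        grid = LabeledGrid.full_solid(6, 1.0)
        with pytest.raises(ConfigurationError):
            build_fe_model(grid, materials, LoadCase())

    def test_interface_nodes_shared(self, tiny_grid, materials):
        # tie constraint by construction: adjacent elements of different
        # materials reference identical node ids on their common face
        model = build_fe_model(tiny_grid, materials, LoadCase())
        total_refs = model.elem_nodes.size
        assert total_refs == 8 * model.n_elements
        assert model.elem_nodes.max() == model.n_nodes - 1


class TestSolve:
    def test_zero_load_zero_fields(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials,
                               LoadCase(mode="compression", F_UA=0.0))
        result = solve_consolidation(model)
        assert np.allclose(result.displacements, 0.0)
        assert np.allclose(result.pressures, 0.0)

    def test_linearity_in_load(self, tiny_grid, materials):
        r1 = solve_consolidation(
            build_fe_model(tiny_grid, materials, LoadCase(F_UA=0.1, n_increments=3)))
        r2 = solve_consolidation(
            build_fe_model(tiny_grid, materials, LoadCase(F_UA=0.2, n_increments=3)))
        np.testing.assert_allclose(r2.displacements, 2 * r1.displacements,
                                   rtol=1e-8, atol=1e-14)
        np.testing.assert_allclose(r2.pressures, 2 * r1.pressures,
                                   rtol=1e-8, atol=1e-14)

    def test_system_matrices_symmetric(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials, LoadCase())
        for M in (model.K, model.H, model.S):
            d = (M - M.T)
            assert abs(d).max() < 1e-10

    def test_equilibrium_base_balances_plate(self, tiny_result):
        model = tiny_result.model
        reaction = base_reaction(tiny_result)
        applied = model.plate_force
        assert np.linalg.norm(reaction + applied) <= 1e-6 * np.linalg.norm(applied)

    def test_shear_mode_reaction(self, tiny_grid, materials):
        model = build_fe_model(tiny_grid, materials,
                               LoadCase(mode="shear", F_UA=0.1, n_increments=3))
        result = solve_consolidation(model)
        reaction = base_reaction(result)
        assert np.linalg.norm(reaction + model.plate_force) <= 1e-6 * np.linalg.norm(
            model.plate_force)

    def test_undrained_stiffer_than_drained(self, materials):
        # step-loaded column: first-increment displacement below the drained one
        mat = materials["granulation"]
        model = build_column_model(mat, 8, 1.0, F_UA=0.05, n_increments=30)
        result = solve_consolidation(model)
        u_first = abs(result.plate_displacement[1, 2])
        u_final = abs(result.plate_displacement[-1, 2])
        assert u_first <= u_final
        assert u_first > 0


class TestTerzaghi:
    @pytest.mark.parametrize("n_elem,n_inc,tol", [(16, 60, 0.02), (32, 240, 0.01)])
    def test_pressure_profiles_match_series(self, materials, n_elem, n_inc, tol):
        mat = materials["granulation"]
        H, sigma0 = 1.0, 0.1
        model = build_column_model(mat, n_elem, H, sigma0, n_increments=n_inc)
        result = solve_consolidation(model)
        cv = mat.consolidation_coefficient
        for Tv in (0.1, 0.3, 0.5):
            t_target = Tv * H * H / cv
            i = int(np.argmin(np.abs(result.times - t_target)))
            z = model.node_coords[:, 2]
            p_ref = terzaghi_pressure(mat, z, result.times[i], H, sigma0)
            rel = np.linalg.norm(result.pressures[i] - p_ref) / np.linalg.norm(p_ref)
            assert rel < tol, (Tv, rel)

    def test_error_decreases_with_refinement(self, materials):
        mat = materials["granulation"]
        H, sigma0 = 1.0, 0.1
        errs = []
        for n_elem, n_inc in ((8, 20), (16, 80)):
            model = build_column_model(mat, n_elem, H, sigma0, n_increments=n_inc)
            result = solve_consolidation(model)
            cv = mat.consolidation_coefficient
            t_target = 0.3 * H * H / cv
            i = int(np.argmin(np.abs(result.times - t_target)))
            p_ref = terzaghi_pressure(mat, model.node_coords[:, 2],
                                      result.times[i], H, sigma0)
            errs.append(np.linalg.norm(result.pressures[i] - p_ref)
                        / np.linalg.norm(p_ref))
        assert errs[1] < errs[0]


class TestElementStrains:
    def _result_with_displacement(self, tiny_result, fn):
        model = tiny_result.model
        u = np.array([fn(xyz) for xyz in model.node_coords])
        nt = 2
        disp = np.zeros((nt, model.n_nodes, 3))
        disp[-1] = u
        return FEMResult(
            model=model,
            times=np.array([0.0, 1.0]),
            displacements=disp,
            pressures=np.zeros((nt, model.n_nodes)),
            plate_displacement=np.zeros((nt, 3)),
        )

    def test_rigid_translation_zero_strain(self, tiny_result):
        r = self._result_with_displacement(tiny_result, lambda p: [0.3, -0.2, 0.1])
        assert np.allclose(element_strains(r), 0.0, atol=1e-12)

    def test_uniaxial_patch(self, tiny_result):
        alpha = 1e-3
        r = self._result_with_displacement(tiny_result, lambda p: [0, 0, alpha * p[2]])
        eps = element_strains(r)
        assert np.allclose(eps[:, 2], alpha, atol=1e-12)
        assert np.allclose(eps[:, [0, 1, 3, 4, 5]], 0.0, atol=1e-12)

    def test_against_central_difference_oracle(self, tiny_result, rng):
        model = tiny_result.model
        u = rng.normal(size=(model.n_nodes, 3)) * 1e-3
        nt = 1
        r = FEMResult(
            model=model,
            times=np.array([1.0]),
            displacements=u[None],
            pressures=np.zeros((nt, model.n_nodes)),
            plate_displacement=np.zeros((nt, 3)),
        )
        eps = element_strains(r, increment=0)
        # independent oracle: trilinear centroid gradient equals the mean of
        # the four node-pair differences along each axis of the hexahedron
        h = model.h
        en = model.elem_nodes
        ue = u[en]  # (ne,8,3)
        # local node order: offsets (0,0,0),(1,0,0),(0,1,0),(1,1,0),(0,0,1)...
        ddx = (ue[:, [1, 3, 5, 7]] - ue[:, [0, 2, 4, 6]]).mean(axis=1) / h
        ddy = (ue[:, [2, 3, 6, 7]] - ue[:, [0, 1, 4, 5]]).mean(axis=1) / h
        ddz = (ue[:, [4, 5, 6, 7]] - ue[:, [0, 1, 2, 3]]).mean(axis=1) / h
        np.testing.assert_allclose(eps[:, 0], ddx[:, 0], atol=1e-8)
        np.testing.assert_allclose(eps[:, 1], ddy[:, 1], atol=1e-8)
        np.testing.assert_allclose(eps[:, 2], ddz[:, 2], atol=1e-8)
        np.testing.assert_allclose(eps[:, 3], ddx[:, 1] + ddy[:, 0], atol=1e-8)
        np.testing.assert_allclose(eps[:, 4], ddy[:, 2] + ddz[:, 1], atol=1e-8)
        np.testing.assert_allclose(eps[:, 5], ddx[:, 2] + ddz[:, 0], atol=1e-8)


class TestDarcyVelocities:
    def _result_with_pressure(self, tiny_result, fn):
        model = tiny_result.model
        p = np.array([fn(xyz) for xyz in model.node_coords])
        r = FEMResult(
            model=model,
            times=np.array([1.0]),
            displacements=np.zeros((1, model.n_nodes, 3)),
            pressures=p[None],
            plate_displacement=np.zeros((1, 3)),
        )
        return r

    def test_uniform_pressure_zero_velocity(self, tiny_result):
        r = self._result_with_pressure(tiny_result, lambda p: 2.5)
        assert np.allclose(darcy_velocities(r, increment=0), 0.0, atol=1e-9)

    def test_unit_gradient_conversion(self, tiny_result):
        # 1 MPa drop per mm with k = 1e-2 mm^4/(N s) -> |v| = 10 um/s
        r = self._result_with_pressure(tiny_result, lambda p: -1.0 * p[2])
        v = darcy_velocities(r, increment=0)
        assert np.allclose(np.abs(v[:, 2]), 10.0, rtol=1e-9)
        assert np.allclose(v[:, :2], 0.0, atol=1e-9)

    def test_velocity_linear_in_permeability(self, tiny_grid):
        mats = default_materials()
        double = {
            name: MaterialProperties(m.E, m.nu, 2 * m.k, m.porosity, m.K_grain, m.K_fluid)
            for name, m in mats.items()
        }
        r1 = self._result_with_pressure_for(tiny_grid, mats)
        r2 = self._result_with_pressure_for(tiny_grid, double)
        v1 = darcy_velocities(r1, increment=0)
        v2 = darcy_velocities(r2, increment=0)
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)

    def _result_with_pressure_for(self, grid, mats):
        model = build_fe_model(grid, mats, LoadCase())
        p = model.node_coords[:, 0] * 0.5 + model.node_coords[:, 1]
        return FEMResult(
            model=model,
            times=np.array([1.0]),
            displacements=np.zeros((1, model.n_nodes, 3)),
            pressures=p[None],
            plate_displacement=np.zeros((1, 3)),
        )


class TestApparentModulus:
    def test_homogeneous_cube_uniaxial(self, materials):
        grid = LabeledGrid.full_solid(6, 1.0)
        load = LoadCase(mode="compression", F_UA=0.1, n_increments=4,
                        hold_time=20.0, n_hold=4)
        model = build_fe_model(grid, materials, load, solid_only=True,
                               plate_tie="normal", base="roller")
        result = solve_consolidation(model)
        assert apparent_modulus(result, 0.1, 1.0) == pytest.approx(1000.0, rel=5e-3)

    def test_direct_arithmetic(self, tiny_result):
        # E_app = F_UA * L / u2 with u2 = 0.001 mm, L = 2.548 mm
        model = tiny_result.model
        r = FEMResult(
            model=model,
            times=np.array([1.0]),
            displacements=np.zeros((1, model.n_nodes, 3)),
            pressures=np.zeros((1, model.n_nodes)),
            plate_displacement=np.array([[0.0, 0.0, -0.001]]),
        )
        assert apparent_modulus(r, 0.1, 2.548) == pytest.approx(254.8)

    def test_zero_displacement_degenerate(self, tiny_result):
        model = tiny_result.model
        r = FEMResult(
            model=model,
            times=np.array([1.0]),
            displacements=np.zeros((1, model.n_nodes, 3)),
            pressures=np.zeros((1, model.n_nodes)),
            plate_displacement=np.zeros((1, 3)),
        )
        with pytest.raises(fem.NumericalError):
            apparent_modulus(r, 0.1, 2.548)
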