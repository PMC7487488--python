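"""Linear tetrahedral elasticity: patch test, closed forms, conservation."""
import numpy as np
import pytest

from femwba import (
    FemurParams,
    LoadCase,
    MaterialSpec,
    ParameterError,
    SolverError,
    TetModel,
    assemble_and_solve,
    build_load_case,
    compare_load_cases,
    extract_path,
    generate_box_tet_mesh,
    generate_tet_mesh,
    principal_stresses,
    tet4_to_tet10,
    von_mises,
)
from femwba.fe_solver import (
    assemble_stiffness,
    node_dofs,
    solve_displacements,
    compute_stress,
    tributary_weights,
)

MAT = MaterialSpec(materials={"cortical": (1000.0, 0.3)})
MAT_NU0 = MaterialSpec(materials={"cortical": (1000.0, 0.0)})


class TestVonMisesAndPrincipal:
    def test_hydrostatic_state_is_zero(self):
        assert von_mises([5.0, 5.0, 5.0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_state_returns_sigma(self):
        assert von_mises([7.0, 0, 0, 0, 0, 0]) == pytest.approx(7.0)

    def test_pure_shear_is_sqrt3_tau(self):
        assert von_mises([0, 0, 0, 2.0, 0, 0]) == pytest.approx(2.0 * np.sqrt(3))

    def test_principal_sorted_descending(self):
        vals = principal_stresses([1.0, 5.0, -2.0, 0, 0, 0])
        assert np.allclose(vals, [5.0, 1.0, -2.0])

    def test_principal_of_shear_state(self):
        vals = principal_stresses([0, 0, 0, 3.0, 0, 0])
        assert np.allclose(vals, [3.0, 0.0, -3.0], atol=1e-12)


class TestPatchTestAndEquilibrium:
    @pytest.mark.parametrize("element_type", ["tet4", "tet10"])
    def test_constant_strain_patch_test(self, element_type):
        """Affine boundary displacements reproduce constant strain exactly."""
        model = generate_box_tet_mesh((3, 3, 3), 1.0)
        if element_type == "tet10":
            model = tet4_to_tet10(model)
        A = np.array([[2e-3, 5e-4, 0.0], [0.0, -1e-3, 3e-4], [1e-4, 0.0, 1.5e-3]])
        bn = model.boundary_nodes()
        uvals = (model.nodes[bn] @ A.T).ravel()
        K = assemble_stiffness(model, MAT)
        u, _, _ = solve_displacements(K, np.zeros(3 * model.n_nodes), bn, uvals)
        stress, strain = compute_stress(model, MAT, u)
        spread = np.abs(strain - strain[0]).max()
        assert spread < 1e-10 * np.abs(strain[0]).max()

    def test_zero_load_gives_zero_field(self):
        model = generate_box_tet_mesh((2, 2, 2), 1.0)
        fixed = np.flatnonzero(model.nodes[:, 2] < 1e-9)
        case = LoadCase("C_point", (0, 0, 1e-30), np.array([int(model.n_nodes - 1)]), np.array([1.0]))
        field, _, _ = assemble_and_solve(model, MAT, case, fixed)
        assert np.abs(field.displacements).max() < 1e-12
        assert np.abs(field.von_mises).max() < 1e-12

    def test_uniaxial_compression_closed_form(self):
        """nu=0 cube, clamped base, uniform top traction: sigma_zz uniform."""
        model = generate_box_tet_mesh((2, 2, 2), 0.5)
        fixed = np.flatnonzero(model.nodes[:, 2] < 1e-9)
        top = np.flatnonzero(model.nodes[:, 2] > 2 - 1e-9)
        w = tributary_weights(model, top)
        case = LoadCase("A_patch", (0.0, 0.0, -4.0), top, w)  # 1 MPa over 4 mm^2
        field, _, _ = assemble_and_solve(model, MAT_NU0, case, fixed)
        assert np.allclose(field.stress[:, 2], -1.0, atol=1e-8)
        assert field.displacements[top, 2].mean() == pytest.approx(-2.0 / 1000.0, rel=1e-6)

    def test_equilibrium_and_energy_consistency(self):
        model = generate_box_tet_mesh((4, 2, 2), 0.5)
        fixed = np.flatnonzero(model.nodes[:, 0] < 1e-9)
        tip = np.flatnonzero(model.nodes[:, 0] > 4 - 1e-9)
        case = LoadCase("A_patch", (0.0, 1.0, -2.0), tip, tributary_weights(model, tip))
        field, _, _ = assemble_and_solve(model, MAT, case, fixed)
        assert field.equilibrium_residual() < 1e-8
        work = 0.5 * field.applied @ field.displacements.ravel()
        assert field.strain_energy == pytest.approx(work, rel=1e-8)

    def test_stiffness_spd_after_constraints(self):
        model = generate_box_tet_mesh((2, 2, 2), 1.0)
        K = assemble_stiffness(model, MAT)
        fixed = np.flatnonzero(model.nodes[:, 2] < 1e-9)
        free = np.setdiff1d(np.arange(3 * model.n_nodes), node_dofs(fixed))
        Kff = K[free][:, free].toarray()
        assert np.allclose(Kff, Kff.T, atol=1e-9)
        assert np.linalg.eigvalsh(Kff).min() > 0

    def test_solution_invariant_under_node_renumbering(self):
        model = generate_box_tet_mesh((3, 2, 2), 1.0)
        fixed = np.flatnonzero(model.nodes[:, 0] < 1e-9)
        tip = np.flatnonzero(model.nodes[:, 0] > 3 - 1e-9)
        case = LoadCase("A_patch", (0, 0, -1.0), tip, tributary_weights(model, tip))
        f1, _, _ = assemble_and_solve(model, MAT, case, fixed)
        rng = np.random.default_rng(0)
        perm = rng.permutation(model.n_nodes)
        inv = np.argsort(perm)
        model2 = TetModel(
            nodes=model.nodes[perm],
            elements=inv[model.elements],
            labels=model.labels,
            element_type="tet4",
        )
        case2 = LoadCase("A_patch", (0, 0, -1.0), inv[tip], case.weights)
        f2, _, _ = assemble_and_solve(model2, MAT, case2, inv[fixed])
        assert np.allclose(f2.displacements[inv[tip]], f1.displacements[tip], atol=1e-8)

    def test_no_constraints_raises(self):
        model = generate_box_tet_mesh((2, 2, 2), 1.0)
        case = LoadCase("C_point", (0, 0, -1.0), np.array([0]), np.array([1.0]))
        with pytest.raises(SolverError):
            assemble_and_solve(model, MAT, case, np.array([], dtype=int))

    def test_inverted_element_rejected(self):
        model = generate_box_tet_mesh((2, 2, 2), 1.0)
        el = model.elements.copy()
        el[0, [0, 1]] = el[0, [1, 0]]  # flip orientation
        bad = TetModel(nodes=model.nodes, elements=el, labels=model.labels)
        with pytest.raises(SolverError):
            assemble_stiffness(bad, MAT)


@pytest.fixture(scope="module")
def femur_model():
    return generate_tet_mesh(FemurParams(), voxel_size=4.0)


class TestLoadCases:
    def test_case_c_is_single_node_full_force(self, femur_model):
        bn = femur_model.boundary_nodes()
        apex = int(bn[np.argmax(femur_model.nodes[bn, 2])])
        case = build_load_case(femur_model, "C_point", (10, -5, -100), apex_node=apex)
        f = case.force_vector(femur_model.n_nodes)
        assert np.count_nonzero(f.reshape(-1, 3).any(axis=1)) == 1
        assert np.allclose(f.reshape(-1, 3)[apex], [10, -5, -100])

    def test_case_b_conserves_total_force(self, femur_model):
        bn = femur_model.boundary_nodes()
        apex = int(bn[np.argmax(femur_model.nodes[bn, 2])])
        case = build_load_case(
            femur_model, "B_circle", (3.0, 7.0, -1111.0),
            circle_center=femur_model.nodes[apex], circle_diameter=20.0,
        )
        f = case.force_vector(femur_model.n_nodes).reshape(-1, 3).sum(axis=0)
        assert np.allclose(f, [3.0, 7.0, -1111.0], rtol=1e-12)

    def test_tributary_load_centroid_stable_under_refinement(self):
        """Doubling mesh density moves the load centroid by < 1%."""
        def load_centroid(voxel):
            m = generate_box_tet_mesh((8, 8, 4), voxel)
            top = np.flatnonzero(m.nodes[:, 2] > 4 - 1e-9)
            w = tributary_weights(m, top)
            return (w[:, None] * m.nodes[top]).sum(axis=0)

        c1 = load_centroid(1.0)
        c2 = load_centroid(0.5)
        assert np.linalg.norm(c1 - c2) < 0.01 * 8.0

    def test_unknown_kind_rejected(self, femur_model):
        with pytest.raises(ParameterError):
            build_load_case(femur_model, "D_other", (0, 0, -1))

    def test_empty_circle_region_rejected(self, femur_model):
        with pytest.raises(ParameterError):
            build_load_case(
                femur_model, "B_circle", (0, 0, -1),
                circle_center=(500.0, 500.0, 500.0), circle_diameter=5.0,
            )


class TestStressPath:
    def test_uniform_field_gives_equal_samples(self):
        model = generate_box_tet_mesh((2, 2, 6), 0.5)
        fixed = np.flatnonzero(model.nodes[:, 2] < 1e-9)
        top = np.flatnonzero(model.nodes[:, 2] > 6 - 1e-9)
        case = LoadCase("A_patch", (0, 0, -4.0), top, tributary_weights(model, top))
        field, _, _ = assemble_and_solve(model, MAT_NU0, case, fixed)
        path = extract_path(field, model, (1, 1, 0.5), (1, 1, 5.5), n_samples=12)
        assert len(path.von_mises) == 12
        assert np.allclose(path.von_mises, path.von_mises[0], rtol=1e-6)
        assert np.all(np.diff(path.arc_positions) > 0)

    def test_single_sample_sits_at_midpoint(self):
        model = generate_box_tet_mesh((2, 2, 6), 1.0)
        fixed = np.flatnonzero(model.nodes[:, 2] < 1e-9)
        case = LoadCase("C_point", (0, 0, -1.0), np.array([int(model.n_nodes - 1)]), np.array([1.0]))
        field, _, _ = assemble_and_solve(model, MAT, case, fixed)
        path = extract_path(field, model, (1, 1, 0), (1, 1, 6), n_samples=1)
        assert path.arc_positions[0] == pytest.approx(3.0)

    def test_coincident_endpoints_rejected(self):
        model = generate_box_tet_mesh((2, 2, 2), 1.0)
        fixed = np.flatnonzero(model.nodes[:, 2] < 1e-9)
        case = LoadCase("C_point", (0, 0, -1.0), np.array([int(model.n_nodes - 1)]), np.array([1.0]))
        field, _, _ = assemble_and_solve(model, MAT, case, fixed)
        with pytest.raises(ParameterError):
            extract_path(field, model, (1, 1, 1), (1, 1, 1))


class TestCompareLoadCases:
    def test_identical_cases_produce_identical_reports(self):
        model = generate_tet_mesh(FemurParams(), voxel_size=4.0)
        z = model.nodes[:, 2]
        fixed = np.flatnonzero(z < z.min() + 1e-9)
        bn = model.boundary_nodes()
        apex = int(bn[np.argmax(model.nodes[bn, 2])])
        mk = lambda: build_load_case(
            model, "B_circle", (0, 0, -1000.0),
            circle_center=model.nodes[apex], circle_diameter=20.0,
        )
        rep = compare_load_cases(model, MaterialSpec(), {"x": mk(), "y": mk()}, fixed)
        fx, fy = rep["_fields"]["x"], rep["_fields"]["y"]
        assert np.array_equal(fx.displacements, fy.displacements)
        assert np.array_equal(fx.von_mises, fy.von_mises)
        for case in rep["cases"].values():
            assert case["equilibrium_residual"] < 1e-8
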