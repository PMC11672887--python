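"""FEM core: symmetry, null space, patch test, scaling laws, increments."""

import numpy as np
import pytest
from scipy.linalg import eigh

from orbitmech import (
    BoundaryConditions,
    MaterialParams,
    Tissue,
    WallTag,
    assemble,
    simulate_scenario,
    solve,
    solve_incremental,
)
from orbitmech.benchmarks import box_mesh
from orbitmech.elasticity import ElementInversionError, SingularSystemError
from orbitmech.surgery import SurgicalPlan


@pytest.fixture(scope="module")
def small_box():
    return box_mesh((10.0, 10.0, 10.0), (2, 2, 2))


@pytest.fixture(scope="module")
def mats():
    return MaterialParams(E={int(Tissue.FAT): 5.0}, nu={int(Tissue.FAT): 0.3})


def test_stiffness_is_symmetric(small_box, mats):
    K = assemble(small_box, mats).K
    asym = abs(K - K.T).max()
    assert asym <= 1e-12 * abs(K).max()


def test_unconstrained_stiffness_has_exactly_six_zero_modes(small_box, mats):
    """Dense eigensolve oracle: the free-floating solid has precisely the
    3 translations + 3 rotations in its null space."""
    K = assemble(small_box, mats).K.toarray()
    w = eigh(K, eigvals_only=True)
    scale = w.max()
    assert np.sum(w < 1e-10 * scale) == 6
    assert w[6] > 1e-6 * scale


def test_operator_linear_in_youngs_modulus(small_box, mats):
    K1 = assemble(small_box, mats).K
    K2 = assemble(small_box, mats.scaled(2.0)).K
    assert abs(K2 - 2.0 * K1).max() <= 1e-12 * abs(K2).max()


def test_missing_material_rejected(small_box):
    bad = MaterialParams(E={int(Tissue.MUSCLE): 1.0}, nu={int(Tissue.MUSCLE): 0.3})
    with pytest.raises(ValueError, match="missing material"):
        assemble(small_box, bad)


def test_zero_loads_zero_dirichlet_gives_zero_field(small_box, mats):
    bc = BoundaryConditions()
    bc.add_dirichlet(small_box.boundary_nodes()[:12], np.zeros(3))
    fld = solve(assemble(small_box, mats), bc)
    assert np.allclose(fld.u, 0.0, atol=1e-14)


def test_patch_test_affine_field_reproduced_exactly(mats):
    """P1 elements reproduce affine displacement fields at interior nodes
    to machine precision."""
    mesh = box_mesh((10.0, 10.0, 10.0), (3, 3, 3))
    A = np.array([[0.01, 0.002, 0.0], [0.0, 0.015, 0.003], [0.001, 0.0, 0.02]])
    b = np.array([0.1, -0.05, 0.02])
    bn = mesh.boundary_nodes()
    bc = BoundaryConditions()
    bc.add_dirichlet(bn, mesh.nodes[bn] @ A.T + b)
    fld = solve(assemble(mesh, mats), bc)
    exact = mesh.nodes @ A.T + b
    assert np.abs(fld.u - exact).max() <= 1e-10 * np.abs(exact).max()


def test_dirichlet_values_reproduced_exactly(small_box, mats):
    bn = small_box.boundary_nodes()
    vals = np.column_stack([0.01 * bn, np.zeros_like(bn), 0.02 * bn]).astype(float)
    bc = BoundaryConditions()
    bc.add_dirichlet(bn, vals)
    fld = solve(assemble(small_box, mats), bc)
    assert np.array_equal(fld.u[bn], vals)


def test_insufficient_constraints_raise_singular_error(small_box, mats):
    bc = BoundaryConditions()  # nothing fixed at all
    with pytest.raises(SingularSystemError):
        solve(assemble(small_box, mats), bc)


def _pressurized_box_bcs(mesh, p):
    """Fix -y face, pressurize +y face."""
    bc = BoundaryConditions()
    fixed = mesh.facets_with_tag(WallTag.APEX_FIXED)
    bc.add_dirichlet(np.unique(mesh.boundary_facets[fixed]), np.zeros(3))
    for fi in mesh.facets_with_tag(WallTag.ANTERIOR_FREE):
        bc.neumann[int(fi)] = ("pressure", p)
    return bc


def test_traction_solution_scales_with_p_over_e(small_box, mats):
    """u depends on pressure and stiffness only through p/E."""
    u1 = solve(assemble(small_box, mats), _pressurized_box_bcs(small_box, 0.1)).u
    u2 = solve(
        assemble(small_box, mats.scaled(3.0)), _pressurized_box_bcs(small_box, 0.3)
    ).u
    assert np.allclose(u1, u2, rtol=1e-9, atol=1e-12)
    u3 = solve(assemble(small_box, mats), _pressurized_box_bcs(small_box, 0.2)).u
    assert np.allclose(u3, 2.0 * u1, rtol=1e-9, atol=1e-12)


def test_dirichlet_solution_independent_of_global_e_scale(small_box, mats):
    bn = small_box.boundary_nodes()
    vals = 0.02 * small_box.nodes[bn]
    bc = BoundaryConditions()
    bc.add_dirichlet(bn, vals)
    u1 = solve(assemble(small_box, mats), bc).u
    u2 = solve(assemble(small_box, mats.scaled(7.0)), bc).u
    assert np.allclose(u1, u2, rtol=1e-9, atol=1e-13)


def test_strain_energy_nonnegative_and_zero_for_rigid_motion(small_box, mats):
    system = assemble(small_box, mats)
    rigid = np.tile([0.3, -0.2, 0.5], (small_box.n_nodes, 1))
    assert abs(system.strain_energy(rigid)) <= 1e-9
    fld = solve(system, _pressurized_box_bcs(small_box, 0.1))
    assert system.strain_energy(fld.u) > 0


def test_single_increment_equals_direct_solve(small_box, mats):
    bc = _pressurized_box_bcs(small_box, 0.1)
    u_direct = solve(assemble(small_box, mats), bc).u
    u_inc = solve_incremental(small_box, mats, bc, n_steps=1).u
    assert np.allclose(u_inc, u_direct, rtol=1e-12, atol=1e-15)


def test_incremental_linear_limit_for_tiny_loads(small_box, mats):
    """As the load vanishes, incremental and one-shot solves coincide."""
    gaps = []
    for p in (1e-2, 1e-4):
        bc = _pressurized_box_bcs(small_box, p)
        u1 = solve_incremental(small_box, mats, bc, n_steps=1).u
        u10 = solve_incremental(small_box, mats, bc, n_steps=10).u
        gaps.append(np.abs(u10 - u1).max() / max(np.abs(u1).max(), 1e-300))
    assert gaps[1] < gaps[0]


def test_incremental_self_convergence(small_box, mats):
    """||u(2k) - u(k)|| shrinks as the step count doubles."""
    bc = _pressurized_box_bcs(small_box, 1.0)  # moderate: ~10% strain
    u = {k: solve_incremental(small_box, mats, bc, n_steps=k).u
         for k in (5, 10, 20)}
    d1 = np.linalg.norm(u[10] - u[5])
    d2 = np.linalg.norm(u[20] - u[10])
    assert d2 < d1


def test_element_inversion_aborts_with_step_and_tet(small_box, mats):
    bc = BoundaryConditions()
    top = small_box.facets_with_tag(WallTag.ANTERIOR_FREE)
    bottom = small_box.facets_with_tag(WallTag.APEX_FIXED)
    bc.add_dirichlet(np.unique(small_box.boundary_facets[bottom]), np.zeros(3))
    bc.add_dirichlet(
        np.unique(small_box.boundary_facets[top]), np.array([0.0, -20.0, 0.0])
    )  # crush the 10 mm box by 20 mm
    with pytest.raises(ElementInversionError) as ei:
        solve_incremental(small_box, mats, bc, n_steps=4)
    assert ei.value.step >= 1
    assert ei.value.tet_id >= 0


def test_resection_without_pressure_gives_zero_field(mesh_te2, materials,
                                                     phantom_default):
    vol, _ = phantom_default
    plan = SurgicalPlan(
        scenario="RESECTION",
        wall_selections=[(WallTag.FLOOR_WALL, None)],
        pressure_kpa=0.0,
    )
    res = simulate_scenario(mesh_te2, plan, materials, n_steps=2, obstacle=vol)
    assert np.allclose(res.field.u, 0.0, atol=1e-12)


def test_identity_valgization_gives_zero_field(mesh_te2, materials):
    plan = SurgicalPlan(
        scenario="VALGIZATION",
        wall_selections=[(WallTag.LATERAL_WALL, None)],
        shift_mm=0.0, angle_deg=0.0, pressure_kpa=0.0,
    )
    res = simulate_scenario(mesh_te2, plan, materials, n_steps=2)
    assert np.allclose(res.field.u, 0.0, atol=1e-12)


def test_valgization_first_step_matches_direct_solve(mesh_te2, materials):
    """One-increment step (i) equals solve() with the compiled step-(i)
    boundary conditions."""
    from orbitmech import compile_boundary_conditions

    plan = SurgicalPlan(
        scenario="VALGIZATION",
        wall_selections=[(WallTag.LATERAL_WALL, None)],
        shift_mm=1.0, angle_deg=5.0, pressure_kpa=0.0,
        blend_mm=8.0, release_mm=3.0,
    )
    res = simulate_scenario(mesh_te2, plan, materials, n_steps=1)
    bc1 = compile_boundary_conditions(mesh_te2, plan)[0]
    direct = solve(assemble(mesh_te2, materials), bc1)
    assert np.allclose(res.step_fields[0].u, direct.u, rtol=1e-9, atol=1e-12)
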