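"""Fragment selection, valgization transforms, BC compilation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orbitmech import (
    Tissue,
    WallTag,
    compile_boundary_conditions,
    make_valgization,
    select_wall_fragment,
)
from orbitmech.benchmarks import box_mesh
from orbitmech.pipeline import default_lava_plan, default_twowall_plan
from orbitmech.surgery import PlanError, SurgicalPlan, _check_contiguous


def test_cube_face_fragment_area():
    """Full +x face of a 10 mm cube is exactly 1.00 cm^2."""
    mesh = box_mesh((10.0, 10.0, 10.0), (4, 4, 4))
    frag = select_wall_fragment(mesh, WallTag.LATERAL_WALL)
    assert frag.area_cm2 == pytest.approx(1.0, rel=1e-9)
    assert np.allclose(frag.outward_normal, [1.0, 0.0, 0.0], atol=1e-9)


def test_lateral_sector_area_near_calibrated_scale(mesh_fine):
    """The default lateral fragment sits at the ~9.6 cm^2 fragment scale."""
    gt = mesh_fine.ground_truth
    frag = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL)
    assert frag.area_cm2 == pytest.approx(gt.lateral_area_cm2, rel=0.05)


def test_angular_subsector_matches_frustum_formula(mesh_fine):
    """A theta x y sub-window agrees with the cone frustum area formula."""
    gt = mesh_fine.ground_truth
    cav = gt.cavity
    th0, th1 = -30.0, 10.0
    y0, y1 = 18.0, 42.0
    frag = select_wall_fragment(
        mesh_fine, WallTag.LATERAL_WALL,
        {"theta_range": (th0, th1), "y_range": (y0, y1)},
    )
    r0, r1 = cav.radius_at(y0), cav.radius_at(y1)
    slant = np.hypot(y1 - y0, r1 - r0)
    analytic = np.pi * (r0 + r1) * slant * (th1 - th0) / 360.0
    assert frag.area_mm2 == pytest.approx(analytic, rel=0.03)


def test_empty_and_disconnected_selections_rejected(mesh_fine):
    with pytest.raises(PlanError, match="empty|absent"):
        select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL,
                             {"y_range": (-50.0, -40.0)})
    with pytest.raises(PlanError, match="disconnected"):
        _check_contiguous(np.array([[0, 1, 2], [10, 11, 12]]))


def test_area_additivity_of_disjoint_subfragments(mesh_fine):
    whole = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL,
                                 {"y_range": (15.0, 45.0)})
    # split by facet-centroid y; the two halves partition the whole window
    a = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL,
                             {"y_range": (15.0, 30.0)})
    b = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL,
                             {"y_range": (30.0 + 1e-9, 45.0)})
    assert a.area_mm2 + b.area_mm2 == pytest.approx(whole.area_mm2, rel=1e-9)


def test_identity_valgization_fixes_all_vertices(mesh_fine):
    frag = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL)
    T = make_valgization(frag, 0.0, 0.0)
    pts = mesh_fine.nodes[frag.node_ids(mesh_fine)]
    assert np.allclose(T.apply(pts), pts, atol=1e-12)


def test_rotation_fixes_hinge_axis_and_obeys_chord_formula(mesh_fine):
    frag = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL)
    T = make_valgization(frag, 0.0, 30.0)
    on_axis = frag.hinge_point + 3.7 * frag.hinge_dir
    assert np.linalg.norm(T.displacement(on_axis)) < 1e-9
    # vertex at perpendicular distance d moves by the chord 2 d sin(15 deg)
    pts = mesh_fine.nodes[frag.node_ids(mesh_fine)]
    rel = pts - frag.hinge_point
    d = np.linalg.norm(rel - (rel @ frag.hinge_dir)[:, None] * frag.hinge_dir,
                       axis=1)
    moved = np.linalg.norm(T.displacement(pts), axis=1)
    assert np.allclose(moved, 2.0 * d * np.sin(np.radians(15.0)), atol=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    shift=st.floats(0.0, 6.0),
    angle=st.floats(0.0, 60.0),
)
def test_valgization_transform_is_rigid(mesh_te2, shift, angle):
    """Pairwise vertex distances are preserved to 1e-9 relative."""
    frag = select_wall_fragment(mesh_te2, WallTag.LATERAL_WALL)
    T = make_valgization(frag, shift, angle)
    pts = mesh_te2.nodes[frag.node_ids(mesh_te2)][::7]
    before = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    after_p = T.apply(pts)
    after = np.linalg.norm(after_p[:, None] - after_p[None, :], axis=-1)
    assert np.allclose(after, before, rtol=1e-9, atol=1e-9)


def test_valgization_rotation_sense_is_outward(mesh_fine):
    frag = select_wall_fragment(mesh_fine, WallTag.LATERAL_WALL)
    T = make_valgization(frag, 0.0, 30.0)
    pts = mesh_fine.nodes[frag.node_ids(mesh_fine)]
    mean_outward = T.displacement(pts).mean(axis=0) @ frag.outward_normal
    assert mean_outward > 0


def test_plan_invariants_enforced():
    with pytest.raises(PlanError):
        SurgicalPlan(scenario="RESECTION",
                     wall_selections=[(WallTag.LATERAL_WALL, None)],
                     shift_mm=2.0)
    with pytest.raises(PlanError):
        SurgicalPlan(scenario="VALGIZATION",
                     wall_selections=[(WallTag.LATERAL_WALL, None)],
                     angle_deg=95.0)
    with pytest.raises(PlanError):
        SurgicalPlan(scenario="VALGIZATION",
                     wall_selections=[(WallTag.LATERAL_WALL, None)],
                     pressure_kpa=-1.0)


def test_resection_zero_pressure_gives_zero_tractions(mesh_te2, phantom_default):
    vol, _ = phantom_default
    plan = default_twowall_plan(pressure_kpa=0.0)
    (bc,) = compile_boundary_conditions(mesh_te2, plan, obstacle=vol)
    assert all(val == 0.0 for _, val in bc.neumann.values())
    assert bc.neumann  # the open window exists


def test_valgization_identity_transform_gives_zero_dirichlet(mesh_te2):
    plan = SurgicalPlan(
        scenario="VALGIZATION",
        wall_selections=[(WallTag.LATERAL_WALL, None)],
        shift_mm=0.0, angle_deg=0.0, pressure_kpa=0.0,
    )
    bc1, _ = compile_boundary_conditions(mesh_te2, plan)
    assert all(np.allclose(v, 0.0) for v in bc1.dirichlet.values())


def test_valgization_dirichlet_equals_rigid_transform(mesh_te2):
    """Unblended compile: every contact-band value is exactly the rigid
    transform displacement; the peak matches the fragment's own peak."""
    plan = SurgicalPlan(
        scenario="VALGIZATION",
        wall_selections=[(WallTag.LATERAL_WALL, None)],
        shift_mm=2.5, angle_deg=30.0, pressure_kpa=0.0,
        contact_tol_mm=1.0, blend_mm=0.0, release_mm=0.0,
    )
    frag = select_wall_fragment(mesh_te2, WallTag.LATERAL_WALL)
    T = make_valgization(frag, 2.5, 30.0)
    bc1, _ = compile_boundary_conditions(mesh_te2, plan)
    moving = {
        n: v for n, v in bc1.dirichlet.items() if np.linalg.norm(v) > 0
    }
    assert moving
    for n, v in moving.items():
        assert np.allclose(v, T.displacement(mesh_te2.nodes[n])[0], atol=1e-9)
    frag_disp = np.linalg.norm(
        T.displacement(mesh_te2.nodes[frag.node_ids(mesh_te2)]), axis=1
    )
    max_bc = max(np.linalg.norm(v) for v in moving.values())
    assert max_bc == pytest.approx(frag_disp.max(), rel=0.1)


def test_bc_compilation_is_deterministic(mesh_te2, phantom_default):
    vol, _ = phantom_default
    plan = default_lava_plan()
    a = compile_boundary_conditions(mesh_te2, plan, obstacle=vol)
    b = compile_boundary_conditions(mesh_te2, plan, obstacle=vol)
    for bca, bcb in zip(a, b):
        assert sorted(bca.dirichlet) == sorted(bcb.dirichlet)
        for n in bca.dirichlet:
            assert np.array_equal(bca.dirichlet[n], bcb.dirichlet[n])
        assert bca.neumann == bcb.neumann


def test_temporalis_blocks_lateral_resection_window(mesh_te2, phantom_default):
    """The temporalis body suppresses tractions behind the lateral window,
    while the floor window stays fully pressurized."""
    vol, _ = phantom_default
    plan = default_twowall_plan(pressure_kpa=0.2)
    (bc,) = compile_boundary_conditions(mesh_te2, plan, obstacle=vol)
    lateral = set(mesh_te2.facets_with_tag(WallTag.LATERAL_WALL).tolist())
    floor = set(mesh_te2.facets_with_tag(WallTag.FLOOR_WALL).tolist())
    pressurized = set(bc.neumann)
    assert len(pressurized & lateral) < 0.2 * len(lateral)
    assert len(pressurized & floor) > 0.8 * len(floor)


def test_plan_yaml_roundtrip(tmp_path):
    plan = default_lava_plan()
    plan.to_yaml(tmp_path / "plan.yaml")
    back = SurgicalPlan.from_yaml(tmp_path / "plan.yaml")
    assert back.scenario == plan.scenario
    assert back.shift_mm == plan.shift_mm
    assert back.angle_deg == plan.angle_deg
    assert back._normalized_selections() == plan._normalized_selections()
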