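"""Outcome metrics: released volume oracles, proptosis, comparison table."""

import dataclasses

import numpy as np
import pytest

from orbitmech import (
    DisplacementField,
    MaterialParams,
    Tissue,
    WallTag,
    compare_scenarios,
    compute_outcome,
    proptosis_change,
    released_volume,
    simulate_scenario,
)
from orbitmech.benchmarks import HalfSpace, box_mesh
from orbitmech.outcome import OutcomeReport
from orbitmech.pipeline import default_twowall_plan


@pytest.fixture(scope="module")
def slab():
    mesh = box_mesh((20.0, 10.0, 20.0), (10, 5, 10))
    cavity = HalfSpace((0.0, 10.0, 0.0), (0.0, 1.0, 0.0))
    return mesh, cavity


def test_zero_field_releases_nothing(slab, mesh_te2):
    mesh, cavity = slab
    zero = DisplacementField(u=np.zeros_like(mesh.nodes))
    assert released_volume(mesh, zero, cavity=cavity, resolution_mm=0.5) == 0.0
    zero2 = DisplacementField(u=np.zeros_like(mesh_te2.nodes))
    assert released_volume(mesh_te2, zero2, resolution_mm=0.75) == 0.0


def test_slab_translation_matches_closed_form(slab):
    """Rigid outward translation t of a slab with contact area A releases
    exactly A*t (A = 4 cm^2, t = 0.5 cm -> 2 cm^3)."""
    mesh, cavity = slab
    u = np.zeros_like(mesh.nodes)
    u[:, 1] = 5.0
    fld = DisplacementField(u=u)
    v = released_volume(mesh, fld, cavity=cavity, resolution_mm=0.5)
    assert v == pytest.approx(2.0, rel=0.01)


def test_released_volume_self_converges(mesh_te2, lava_result):
    """Halving the rasterization pitch changes the value by < 1%."""
    v_h2 = released_volume(mesh_te2, lava_result.field, resolution_mm=1.0)
    v_h4 = released_volume(mesh_te2, lava_result.field, resolution_mm=0.5)
    assert v_h2 == pytest.approx(v_h4, rel=0.01)


def test_field_mesh_mismatch_rejected(slab):
    mesh, cavity = slab
    with pytest.raises(ValueError, match="match"):
        released_volume(mesh, DisplacementField(u=np.zeros((3, 3))),
                        cavity=cavity)


def test_proptosis_zero_translation_and_oracle(mesh_te2):
    zero = DisplacementField(u=np.zeros_like(mesh_te2.nodes))
    assert proptosis_change(mesh_te2, zero) == 0.0

    bulbus_nodes = np.unique(
        mesh_te2.tets[mesh_te2.tet_label == int(Tissue.BULBUS)]
    )
    u = np.zeros_like(mesh_te2.nodes)
    u[bulbus_nodes, 1] = -2.0
    assert proptosis_change(mesh_te2, DisplacementField(u=u)) == pytest.approx(2.0)

    # mixed field vs brute-force front-pole comparison
    rng = np.random.default_rng(3)
    u = 0.5 * rng.standard_normal(mesh_te2.nodes.shape)
    fld = DisplacementField(u=u)
    y0 = mesh_te2.nodes[bulbus_nodes, 1].max()
    y1 = (mesh_te2.nodes[bulbus_nodes, 1] + u[bulbus_nodes, 1]).max()
    assert proptosis_change(mesh_te2, fld) == pytest.approx(y0 - y1, abs=1e-12)


def test_proptosis_requires_bulbus(slab):
    mesh, _ = slab  # all-fat box
    with pytest.raises(ValueError, match="bulbus"):
        proptosis_change(mesh, DisplacementField(u=np.zeros_like(mesh.nodes)))


def test_released_volume_monotone_in_pressure(phantom_default, mesh_te4,
                                              materials):
    vol, _ = phantom_default
    flux, voxel = [], []
    for p in (0.05, 0.1, 0.2, 0.4):
        plan = default_twowall_plan(pressure_kpa=p)
        res = simulate_scenario(mesh_te4, plan, materials, n_steps=2,
                                obstacle=vol)
        flux.append(released_volume(mesh_te4, res.field, method="flux"))
        if p >= 0.2:
            voxel.append(released_volume(mesh_te4, res.field,
                                         resolution_mm=0.75))
    assert all(b >= a for a, b in zip(flux, flux[1:]))
    assert flux[-1] > flux[0]
    assert voxel[1] > voxel[0]


def test_flux_mode_tracks_voxel_mode(mesh_te2, twowall_result):
    v_vox = released_volume(mesh_te2, twowall_result.field, resolution_mm=0.5)
    v_flux = released_volume(mesh_te2, twowall_result.field, method="flux")
    assert v_flux == pytest.approx(v_vox, rel=0.15)  # first-order cross-check


def test_outcome_report_arithmetic_and_comparison(mesh_te2, twowall_result):
    rep = compute_outcome(mesh_te2, twowall_result, resolution_mm=1.0)
    assert rep.volume_per_area == pytest.approx(
        rep.released_cm3 / rep.area_cm2, rel=1e-12
    )

    same = OutcomeReport(scenario="a", area_cm2=rep.area_cm2,
                         released_cm3=rep.released_cm3, proptosis_mm=0.0)
    same2 = dataclasses.replace(same, scenario="b")
    df = compare_scenarios([same, same2])
    assert df["ratio_vs_a"].iloc[1] == pytest.approx(1.0)

    doubled = dataclasses.replace(same, scenario="c",
                                  area_cm2=2 * rep.area_cm2)
    df2 = compare_scenarios([same, doubled])
    assert df2["ratio_vs_a"].iloc[1] == pytest.approx(0.5)


def test_invalid_report_rejected():
    with pytest.raises(ValueError):
        OutcomeReport(scenario="x", area_cm2=0.0, released_cm3=1.0,
                      proptosis_mm=0.0)
    with pytest.raises(ValueError):
        OutcomeReport(scenario="x", area_cm2=1.0, released_cm3=-1.0,
                      proptosis_mm=0.0)
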