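"""Surface extraction and tet meshing: analytic oracles and invariants."""

import dataclasses

import numpy as np
import pytest

from orbitmech import (
    LabelVolume,
    PhantomSpec,
    Tissue,
    WallTag,
    build_tet_mesh,
    extract_surfaces,
    generate_phantom,
    mesh_quality,
)
from orbitmech.meshing import TissueMesh, tet_volumes


def test_sphere_isosurface_area_matches_analytic():
    """Marching cubes of a 12 mm sphere at 0.5 mm voxels: area to 3%."""
    h = 0.5
    n = 60
    c = n * h / 2.0
    x = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    mask = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 < 12.0**2
    vol = LabelVolume(labels=mask.astype(np.int16) * int(Tissue.BULBUS),
                      voxel_size=h)
    surf = extract_surfaces(vol, Tissue.BULBUS)
    assert surf.is_closed()
    assert surf.area == pytest.approx(4 * np.pi * 12.0**2, rel=0.03)


def test_cube_isosurface_is_closed_with_correct_volume():
    labels = np.zeros((14, 14, 14), dtype=np.int16)
    labels[2:12, 2:12, 2:12] = int(Tissue.FAT)
    vol = LabelVolume(labels=labels, voxel_size=1.0)
    surf = extract_surfaces(vol, Tissue.FAT)
    assert surf.is_closed()
    assert len(surf.triangles) >= 12
    assert surf.enclosed_volume == pytest.approx(1000.0, rel=0.02)


def test_absent_label_raises_by_name():
    vol = LabelVolume(labels=np.zeros((4, 4, 4), dtype=np.int16), voxel_size=1.0)
    with pytest.raises(ValueError, match="3"):
        extract_surfaces(vol, Tissue.MUSCLE)


def test_all_fat_cube_mesh_volume_exact():
    labels = np.full((10, 10, 10), int(Tissue.FAT), dtype=np.int16)
    vol = LabelVolume(labels=labels, voxel_size=1.0)
    mesh = build_tet_mesh(vol)
    assert mesh.tissue_volume(Tissue.FAT) == pytest.approx(1000.0, rel=0.01)


def test_boundary_tags_partition_exactly(mesh_fine):
    tags = set(np.unique(mesh_fine.facet_tags).tolist())
    assert tags <= {int(t) for t in WallTag}
    assert 0 not in tags  # every facet carries exactly one tag
    assert len(mesh_fine.facet_tags) == len(mesh_fine.boundary_facets)


def test_refinement_increases_nodes_and_shrinks_elements(phantom_default):
    vol, gt = phantom_default
    coarse = build_tet_mesh(vol, target_edge=3.0, ground_truth=gt)
    fine = build_tet_mesh(vol, target_edge=1.5, ground_truth=gt)
    assert fine.n_nodes > coarse.n_nodes
    assert fine.volumes().max() < coarse.volumes().max()


def test_volume_conservation_and_label_fidelity(phantom_default, mesh_fine):
    vol, _ = phantom_default
    for t in (Tissue.FAT, Tissue.MUSCLE, Tissue.BULBUS):
        assert mesh_fine.tissue_volume(t) == pytest.approx(
            vol.tissue_volume(t), rel=0.03
        )
    # centroid label agreement
    cent = mesh_fine.nodes[mesh_fine.tets].mean(axis=1)
    idx = np.floor((cent - vol.origin) / vol.voxel_size).astype(int)
    lab = vol.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    agree = np.mean(lab == mesh_fine.tet_label)
    assert agree >= 0.99


def test_all_tets_positively_oriented(mesh_te2):
    assert (mesh_te2.volumes() > 0).all()


def test_quality_of_regular_tetrahedron():
    nodes = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    tets = np.array([[0, 1, 2, 3]])
    if tet_volumes(nodes, tets)[0] < 0:
        tets = np.array([[0, 1, 3, 2]])
    mesh = TissueMesh(
        nodes=nodes, tets=tets,
        tet_label=np.array([int(Tissue.FAT)]),
        boundary_facets=np.empty((0, 3), dtype=int),
        facet_tags=np.empty(0, dtype=np.int32),
    )
    q = mesh_quality(mesh)
    assert q.min_dihedral_deg == pytest.approx(70.5288, abs=0.01)
    assert q.max_aspect == pytest.approx(1.0, rel=1e-6)
    assert q.inverted_count == 0


def test_inverted_tet_is_detected():
    nodes = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    mesh = TissueMesh(
        nodes=nodes, tets=np.array([[0, 2, 1, 3]]),  # flipped on purpose
        tet_label=np.array([int(Tissue.FAT)]),
        boundary_facets=np.empty((0, 3), dtype=int),
        facet_tags=np.empty(0, dtype=np.int32),
    )
    assert mesh_quality(mesh).inverted_count == 1


def test_default_phantom_mesh_has_no_inverted_tets(mesh_fine):
    assert mesh_quality(mesh_fine).inverted_count == 0


def test_no_deformable_tissue_rejected():
    labels = np.full((6, 6, 6), int(Tissue.BONE), dtype=np.int16)
    with pytest.raises(ValueError, match="deformable"):
        build_tet_mesh(LabelVolume(labels=labels, voxel_size=1.0))


def test_snapped_mesh_is_valid_and_tighter(phantom_default):
    """Optional boundary snapping stays inversion-free and moves the
    boundary closer to the analytic cavity surface."""
    vol, gt = phantom_default
    plain = build_tet_mesh(vol, target_edge=2.0, ground_truth=gt, snap=False)
    snapped = build_tet_mesh(vol, target_edge=2.0, ground_truth=gt, snap=True)
    assert mesh_quality(snapped).inverted_count == 0

    def rms_wall_distance(mesh):
        bn = mesh.boundary_nodes()
        p = mesh.nodes[bn]
        cav = gt.cavity
        rho = np.hypot(p[:, 0] - cav.center_x, p[:, 2] - cav.center_z)
        d = rho - np.asarray(cav.radius_at(p[:, 1]))
        near = np.abs(d) < 2.0
        return np.sqrt(np.mean(d[near] ** 2))

    assert rms_wall_distance(snapped) < rms_wall_distance(plain)
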