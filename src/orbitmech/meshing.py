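"""Surface and tetrahedral model generation from labelmaps.

Surfaces are marching-cubes iso-surfaces of per-tissue binary masks.  The
volumetric mesh is a deterministic Freudenthal (6-tet) subdivision of the
labeled voxel lattice resampled at the requested edge length, with boundary
nodes snapped radially onto the analytic cavity surface when the phantom
geometry is known (snapping is scaled back locally wherever it would invert
an element).  Node-ordering convention: every tet is stored with positive
signed volume det[x1-x0, x2-x0, x3-x0] > 0 (right-handed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
import trimesh.smoothing
from skimage.measure import marching_cubes

from .phantom import (
    DEFORMABLE_TISSUES,
    LabelVolume,
    PhantomGroundTruth,
    Tissue,
    WallTag,
)

__all__ = [
    "SurfaceMesh",
    "TissueMesh",
    "MeshQuality",
    "extract_surfaces",
    "build_tet_mesh",
    "mesh_quality",
    "tet_volumes",
    "facet_areas_normals",
]


@dataclass
class SurfaceMesh:
    """Closed triangulated iso-surface of one tissue (world mm)."""

    vertices: np.ndarray
    triangles: np.ndarray
    tissue_label: int

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def enclosed_volume(self) -> float:
        return float(abs(self.as_trimesh().volume))

    def is_closed(self) -> bool:
        return bool(self.as_trimesh().is_watertight)


@dataclass
class TissueMesh:
    """Labeled tetrahedral soft-tissue mesh with tagged boundary facets."""

    nodes: np.ndarray           # (N, 3) world mm
    tets: np.ndarray            # (M, 4) node indices, positive orientation
    tet_label: np.ndarray       # (M,) tissue code per tet
    boundary_facets: np.ndarray  # (F, 3) node indices, outward orientation
    facet_tags: np.ndarray      # (F,) WallTag codes
    pitch: float = 0.0          # lattice edge length used at build time
    ground_truth: PhantomGroundTruth | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self, nodes: np.ndarray | None = None) -> np.ndarray:
        return tet_volumes(self.nodes if nodes is None else nodes, self.tets)

    def tissue_volume(self, label: int, nodes: np.ndarray | None = None) -> float:
        v = self.volumes(nodes)
        return float(v[self.tet_label == int(label)].sum())

    def facets_with_tag(self, tag: WallTag) -> np.ndarray:
        """Indices into boundary_facets carrying the given tag."""
        return np.flatnonzero(self.facet_tags == int(tag))

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_facets)


@dataclass
class MeshQuality:
    min_dihedral_deg: float
    max_aspect: float
    inverted_count: int
    n_tets: int
    n_nodes: int


# ---------------------------------------------------------------------------
# geometry helpers shared across modules

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tet volumes under the package's right-handed convention."""
    p = nodes[tets]
    m = p[:, 1:] - p[:, :1]
    return np.linalg.det(m) / 6.0


def facet_areas_normals(nodes: np.ndarray, facets: np.ndarray):
    """Areas and unit normals of oriented triangles."""
    p = nodes[facets]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    a2 = np.linalg.norm(cr, axis=1)
    areas = 0.5 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cr / a2[:, None]
    normals[a2 == 0] = 0.0
    return areas, normals


# ---------------------------------------------------------------------------
# iso-surface extraction

def extract_surfaces(volume: LabelVolume, label: int,
                     smooth_iterations: int = 10) -> SurfaceMesh:
    """Marching-cubes iso-surface (iso 0.5) of one tissue's binary mask.

    The mask is zero-padded so surfaces close at the grid border; vertex
    coordinates are world mm; triangles are oriented outward.  The raw
    contour of a binary mask carries the voxel staircase, which inflates
    curved areas; a few shrink-free Taubin smoothing passes remove it
    while preserving the enclosed volume and sharp planar features.
    """
    mask = volume.labels == int(label)
    if not mask.any():
        raise ValueError(f"label {int(label)} not present in volume")
    h = volume.voxel_size
    verts, faces, _, _ = marching_cubes(
        np.pad(mask, 1).astype(np.uint8), level=0.5, spacing=(h, h, h)
    )
    # padded index 1 is voxel 0, whose center sits at origin + 0.5 h
    verts = verts + (volume.origin - 0.5 * h)
    tm = trimesh.Trimesh(verts, faces, process=True)
    if smooth_iterations:
        trimesh.smoothing.filter_taubin(tm, iterations=smooth_iterations)
    faces = np.asarray(tm.faces)
    if tm.volume < 0:
        faces = faces[:, ::-1]
    return SurfaceMesh(vertices=np.asarray(tm.vertices), triangles=faces,
                       tissue_label=int(label))


# ---------------------------------------------------------------------------
# Freudenthal lattice tetrahedralization

# 6 tets of the Kuhn subdivision of the unit cube, as insertion orders of
# the axes along the main diagonal; corners numbered bit-wise (dx,dy,dz).
_KUHN_PERMS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))


def _cube_tets() -> np.ndarray:
    """Local corner indices of the 6 Kuhn tets, positively oriented."""
    corners = np.array([[dx, dy, dz] for dz in (0, 1) for dy in (0, 1)
                        for dx in (0, 1)])

    def cid(v):
        return int(v[0] + 2 * v[1] + 4 * v[2])

    tets = []
    for perm in _KUHN_PERMS:
        v = np.zeros(3, dtype=int)
        path = [cid(v)]
        for ax in perm:
            v = v.copy()
            v[ax] = 1
            path.append(cid(v))
        t = np.array(path)
        m = corners[t[1:]] - corners[t[0]]
        if np.linalg.det(m) < 0:
            t[[2, 3]] = t[[3, 2]]
        tets.append(t)
    return np.array(tets)


_CUBE_TETS = _cube_tets()

# outward-oriented faces of a positively oriented tet (local indices)
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _resample_labels(volume: LabelVolume, pitch: float):
    """Nearest-neighbour label field on a lattice of the given pitch."""
    h = volume.voxel_size
    shape = volume.labels.shape
    dims = tuple(max(1, int(round(s * h / pitch))) for s in shape)
    centers = [
        np.clip(((np.arange(d) + 0.5) * pitch / h).astype(int), 0, s - 1)
        for d, s in zip(dims, shape)
    ]
    lab = volume.labels[np.ix_(*centers)]
    return lab, dims


def build_tet_mesh(
    volume: LabelVolume,
    target_edge: float | None = None,
    ground_truth: PhantomGroundTruth | None = None,
    snap: bool = False,
) -> TissueMesh:
    """Tetrahedralize the deformable tissues (fat, muscle, bulbus).

    Each lattice cell whose center voxel carries a deformable label is split
    into 6 Kuhn tets labeled by that cell.  With ``ground_truth`` supplied,
    boundary facets are tagged by wall sector / apex / anterior aperture;
    without it, facets are tagged by their dominant outward normal axis
    (+y anterior, -y apex, +/-x lateral/medial, +/-z roof/floor).

    ``snap=True`` additionally projects boundary nodes near the conical
    cavity wall radially onto the analytic surface (scaled back locally
    wherever an element would fall below a volume floor).  The default
    keeps the axis-aligned lattice boundary: element quality is then
    uniform (all Kuhn tets), and the staircase bias is compensated
    downstream (wall areas are projected onto the analytic surface,
    released volume is measured against the undeformed occupancy).
    """
    pitch = float(target_edge) if target_edge else volume.voxel_size
    lab, dims = _resample_labels(volume, pitch)
    deform = np.isin(lab, [int(t) for t in DEFORMABLE_TISSUES])
    if not deform.any():
        raise ValueError("volume contains no deformable tissue (codes 2-4)")

    cells = np.argwhere(deform)  # (C, 3) lattice cell indices
    cell_lab = lab[deform]
    nxp, nyp, nzp = (d + 1 for d in dims)

    def corner_id(idx):
        return (idx[:, 0] * nyp + idx[:, 1]) * nzp + idx[:, 2]

    offsets = np.array([[dx, dy, dz] for dz in (0, 1) for dy in (0, 1)
                        for dx in (0, 1)])
    corner_ids = np.stack([corner_id(cells + o) for o in offsets], axis=1)
    uniq, inv = np.unique(corner_ids, return_inverse=True)
    inv = inv.reshape(corner_ids.shape)
    gid = np.stack(np.unravel_index(uniq, (nxp, nyp, nzp)), axis=1)
    nodes = volume.origin + gid * pitch

    tets = inv[:, _CUBE_TETS].reshape(-1, 4)
    tet_label = np.repeat(cell_lab, 6)

    vols = tet_volumes(nodes, tets)
    neg = np.flatnonzero(vols < 0)
    if len(neg):  # orientation is uniform per Kuhn tet; fix defensively
        tets[np.ix_(neg, [2, 3])] = tets[np.ix_(neg, [3, 2])]

    boundary, owner_face = _boundary_facets(tets)

    if ground_truth is not None and snap:
        nodes = _snap_boundary(nodes, tets, boundary, ground_truth, pitch)

    tags = _tag_facets(nodes, boundary, ground_truth, pitch)
    mesh = TissueMesh(
        nodes=nodes,
        tets=tets,
        tet_label=tet_label,
        boundary_facets=boundary,
        facet_tags=tags,
        pitch=pitch,
        ground_truth=ground_truth,
    )
    q = mesh_quality(mesh)
    if q.inverted_count:
        raise RuntimeError(
            f"tet mesh generation produced {q.inverted_count} inverted tets"
        )
    return mesh


def _boundary_facets(tets: np.ndarray):
    """Faces appearing in exactly one tet, outward oriented."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    bidx = first[counts == 1]
    return faces[bidx], bidx // 4


def _snap_boundary(nodes, tets, boundary, gt: PhantomGroundTruth, pitch):
    """Project wall-adjacent boundary nodes radially onto the cone surface.

    Snap amounts are halved (up to full revert) for nodes of any element
    the projection would invert, keeping the mesh valid by construction.
    """
    cav = gt.cavity
    bn = np.unique(boundary)
    p = nodes[bn]
    rho = np.hypot(p[:, 0] - cav.center_x, p[:, 2] - cav.center_z)
    rc = np.asarray(cav.radius_at(p[:, 1]))
    near = (
        (np.abs(rho - rc) < 0.95 * pitch)
        & (p[:, 1] > cav.apex_y + 0.25)
        & (p[:, 1] < cav.rim_y - 1e-9)
        & (rho > 1e-9)
    )
    idx = bn[near]
    scale_r = rc[near] / rho[near]
    target = nodes[idx].copy()
    target[:, 0] = cav.center_x + (target[:, 0] - cav.center_x) * scale_r
    target[:, 2] = cav.center_z + (target[:, 2] - cav.center_z) * scale_r

    # quality floor: lattice tets have volume pitch^3/6; refuse to squash
    # any element below ~10% of that
    vmin = 0.015 * pitch**3
    alpha = np.ones(len(idx))
    base = nodes.copy()
    for _ in range(30):
        snapped = base.copy()
        snapped[idx] = base[idx] + alpha[:, None] * (target - base[idx])
        bad = tet_volumes(snapped, tets) <= vmin
        if not bad.any():
            return snapped
        bad_nodes = np.unique(tets[bad])
        shrink = np.isin(idx, bad_nodes)
        alpha[shrink] *= 0.7
        alpha[shrink & (alpha < 1e-3)] = 0.0
    return snapped if not bad.any() else base


def _tag_facets(nodes, boundary, gt: PhantomGroundTruth | None, pitch):
    areas, normals = facet_areas_normals(nodes, boundary)
    cent = nodes[boundary].mean(axis=1)
    tags = np.zeros(len(boundary), dtype=np.int32)
    if gt is None:
        ax = np.argmax(np.abs(normals), axis=1)
        sgn = np.take_along_axis(normals, ax[:, None], 1)[:, 0] >= 0
        lut = {
            (0, True): WallTag.LATERAL_WALL,
            (0, False): WallTag.MEDIAL_WALL,
            (1, True): WallTag.ANTERIOR_FREE,
            (1, False): WallTag.APEX_FIXED,
            (2, True): WallTag.ROOF_WALL,
            (2, False): WallTag.FLOOR_WALL,
        }
        for (a, s), tag in lut.items():
            tags[(ax == a) & (sgn == s)] = int(tag)
        return tags
    cav = gt.cavity
    spec = gt.spec
    anterior = cent[:, 1] >= cav.rim_y - 0.55 * pitch
    apex_band = max(2.0, 0.8 * pitch)
    apex = (~anterior) & (cent[:, 1] <= cav.apex_y + apex_band)
    theta = np.degrees(np.arctan2(cent[:, 2] - cav.center_z,
                                  cent[:, 0] - cav.center_x))
    tags[:] = spec.sector_of(theta)
    tags[apex] = int(WallTag.APEX_FIXED)
    tags[anterior] = int(WallTag.ANTERIOR_FREE)
    return tags


# ---------------------------------------------------------------------------
# quality metrics

def mesh_quality(mesh: TissueMesh) -> MeshQuality:
    """Min dihedral angle, max aspect ratio, inverted-tet count.

    Aspect ratio is longest-edge over inradius, normalized so a regular
    tetrahedron scores 1.
    """
    if mesh.n_tets == 0:
        raise ValueError("empty mesh")
    p = mesh.nodes[mesh.tets]
    vols = mesh.volumes()
    inverted = int(np.count_nonzero(vols <= 0))

    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(p[:, a] - p[:, b], axis=1)
                      for a, b in pairs], axis=1)
    longest = edges.max(axis=1)

    fareas = np.zeros((mesh.n_tets, 4))
    fnormals = np.zeros((mesh.n_tets, 4, 3))
    for i, f in enumerate(_TET_FACES):
        cr = np.cross(p[:, f[1]] - p[:, f[0]], p[:, f[2]] - p[:, f[0]])
        nrm = np.linalg.norm(cr, axis=1)
        fareas[:, i] = 0.5 * nrm
        fnormals[:, i] = cr / np.maximum(nrm, 1e-300)[:, None]

    inradius = 3.0 * np.abs(vols) / np.maximum(fareas.sum(axis=1), 1e-300)
    aspect = longest * np.sqrt(6.0) / (12.0 * inradius)

    min_dih = 180.0
    for i in range(4):
        for j in range(i + 1, 4):
            cosang = np.clip(-(fnormals[:, i] * fnormals[:, j]).sum(axis=1),
                             -1.0, 1.0)
            min_dih = min(min_dih, float(np.degrees(np.arccos(cosang)).min()))

    return MeshQuality(
        min_dihedral_deg=min_dih,
        max_aspect=float(aspect.max()),
        inverted_count=inverted,
        n_tets=mesh.n_tets,
        n_nodes=mesh.n_nodes,
    )
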