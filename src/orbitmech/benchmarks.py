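"""Verification benchmarks for the elasticity solver.

Provides the classical pressurized thick-walled sphere (Lamé) problem: an
analytically meshed spherical shell, the closed-form radial displacement,
and a driver that applies the internal pressure and measures the relative
L2 displacement error.  Also provides a structured box mesh for patch
tests.  These meshes are geometry-conforming (no voxel staircase), so the
discretization error measured here is the element error itself.
"""

from __future__ import annotations

import numpy as np

from .elasticity import MaterialParams, assemble, solve
from .meshing import TissueMesh, _boundary_facets, tet_volumes
from .phantom import Tissue, WallTag
from .surgery import BoundaryConditions

__all__ = [
    "lame_radial_displacement",
    "spherical_shell_mesh",
    "solve_lame_sphere",
    "box_mesh",
    "HalfSpace",
]


class HalfSpace:
    """Planar cavity descriptor: inside where n . (x - p0) < 0.

    Duck-typed stand-in for the conical cavity in slab fixtures (released
    tissue volume against a flat wall has the closed form A * t).
    """

    def __init__(self, point, normal):
        self.point = np.asarray(point, dtype=float)
        n = np.asarray(normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def signed_distance(self, points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - self.point) @ self.normal

    def contains(self, points):
        return self.signed_distance(points) < 0.0


def lame_radial_displacement(r, a, b, p, E, nu):
    """Radial displacement of a thick-walled sphere (inner radius a, outer
    b) under internal pressure p:

        u(r) = p a^3 / (E (b^3 - a^3)) * [(1-2 nu) r + (1+nu) b^3/(2 r^2)]
    """
    r = np.asarray(r, dtype=float)
    c = p * a**3 / (E * (b**3 - a**3))
    return c * ((1 - 2 * nu) * r + (1 + nu) * b**3 / (2 * r**2))


def _cube_sphere_directions(n: int):
    """Vertex directions of an n x n cube-sphere grid, deduplicated.

    Returns (dirs (V,3) unit vectors, per-face index grids (6, n+1, n+1)).
    """
    u = np.linspace(-1.0, 1.0, n + 1)
    key_map: dict = {}
    dirs: list = []
    face_grids = np.zeros((6, n + 1, n + 1), dtype=int)
    axes = [
        (0, +1), (0, -1), (1, +1), (1, -1), (2, +1), (2, -1),
    ]
    for f, (ax, sgn) in enumerate(axes):
        for i, s in enumerate(u):
            for j, t in enumerate(u):
                v = np.zeros(3)
                v[ax] = sgn
                v[(ax + 1) % 3] = s
                v[(ax + 2) % 3] = t
                v /= np.linalg.norm(v)
                key = tuple(np.round(v, 9))
                if key not in key_map:
                    key_map[key] = len(dirs)
                    dirs.append(v)
                face_grids[f, i, j] = key_map[key]
    return np.array(dirs), face_grids


def spherical_shell_mesh(
    a: float, b: float, n_surf: int = 6, n_rad: int = 4,
    label: int = int(Tissue.FAT),
) -> tuple[TissueMesh, np.ndarray, np.ndarray]:
    """Structured tet mesh of the shell a <= r <= b.

    Cube-sphere surface grid (n_surf x n_surf per face, n_surf even keeps
    exact on-axis nodes) extruded over n_rad radial layers; each
    hexahedral cell is split into 24 tets through its cell and face
    centroids, which is conforming by construction.  Returns
    (mesh, inner_facet_ids, outer_facet_ids) with facet ids indexing
    ``mesh.boundary_facets``.
    """
    dirs, grids = _cube_sphere_directions(n_surf)
    radii = np.linspace(a, b, n_rad + 1)
    nv_surf = len(dirs)
    nodes = [(dirs[None, :, :] * radii[:, None, None]).reshape(-1, 3)]
    n_base = nv_surf * (n_rad + 1)

    def vid(layer, didx):
        return layer * nv_surf + didx

    # hexes: (face, i, j, layer) with 8 corner node ids
    hexes = []
    for f in range(6):
        g = grids[f]
        for i in range(n_surf):
            for j in range(n_surf):
                for k in range(n_rad):
                    c = [
                        vid(k, g[i, j]), vid(k, g[i + 1, j]),
                        vid(k, g[i + 1, j + 1]), vid(k, g[i, j + 1]),
                        vid(k + 1, g[i, j]), vid(k + 1, g[i + 1, j]),
                        vid(k + 1, g[i + 1, j + 1]), vid(k + 1, g[i, j + 1]),
                    ]
                    hexes.append(c)
    hexes = np.array(hexes)
    base_nodes = nodes[0]

    # quad faces of each hex (corner index quadruples)
    quad_local = np.array([
        [0, 1, 2, 3], [4, 7, 6, 5],
        [0, 4, 5, 1], [1, 5, 6, 2], [2, 6, 7, 3], [3, 7, 4, 0],
    ])

    face_key_to_node: dict = {}
    extra_nodes: list = []

    def face_centroid_node(quad_ids):
        key = tuple(sorted(int(q) for q in quad_ids))
        if key in face_key_to_node:
            return face_key_to_node[key]
        nid = n_base + len(extra_nodes)
        extra_nodes.append(base_nodes[list(quad_ids)].mean(axis=0))
        face_key_to_node[key] = nid
        return nid

    tets = []
    for h in hexes:
        cen_id = n_base + len(extra_nodes)
        extra_nodes.append(base_nodes[h].mean(axis=0))
        for ql in quad_local:
            quad = h[ql]
            fc = face_centroid_node(quad)
            if fc == cen_id:  # cannot happen, defensive
                raise RuntimeError
            for e in range(4):
                v0, v1 = int(quad[e]), int(quad[(e + 1) % 4])
                tets.append((cen_id, fc, v0, v1))

    all_nodes = np.vstack([base_nodes] + [np.array(extra_nodes)])
    tets = np.array(tets)
    vols = tet_volumes(all_nodes, tets)
    neg = np.flatnonzero(vols < 0)
    if len(neg):
        tets[np.ix_(neg, [2, 3])] = tets[np.ix_(neg, [3, 2])]
    vols = tet_volumes(all_nodes, tets)
    keep = vols > 1e-12
    tets = tets[keep]

    boundary, _ = _boundary_facets(tets)
    # place boundary nodes (including quad-face centroids) exactly on the
    # spheres so the discrete boundary is nodally exact
    bn = np.unique(boundary)
    rn = np.linalg.norm(all_nodes[bn], axis=1)
    target = np.where(rn < 0.5 * (a + b), a, b)
    all_nodes[bn] *= (target / rn)[:, None]
    if np.any(tet_volumes(all_nodes, tets) <= 0):
        raise RuntimeError("boundary projection inverted an element")
    cent_r = np.linalg.norm(all_nodes[boundary].mean(axis=1), axis=1)
    mid = 0.5 * (a + b)
    inner = np.flatnonzero(cent_r < mid)
    outer = np.flatnonzero(cent_r >= mid)
    tags = np.full(len(boundary), int(WallTag.ANTERIOR_FREE), dtype=np.int32)
    tags[inner] = int(WallTag.MEDIAL_WALL)   # inner surface marker
    tags[outer] = int(WallTag.LATERAL_WALL)  # outer surface marker

    mesh = TissueMesh(
        nodes=all_nodes,
        tets=tets,
        tet_label=np.full(len(tets), int(label), dtype=np.int16),
        boundary_facets=boundary,
        facet_tags=tags,
        pitch=(b - a) / n_rad,
    )
    return mesh, inner, outer


def _axis_point_constraints(mesh: TissueMesh, a: float):
    """Six consistent point constraints removing rigid-body motion without
    disturbing a purely radial field: on-axis inner-surface nodes at
    (+/-a,0,0) lose their tangential dofs, (0,a,0) loses x and z."""
    targets = [
        (np.array([a, 0.0, 0.0]), (1, 2)),
        (np.array([-a, 0.0, 0.0]), (1, 2)),
        (np.array([0.0, a, 0.0]), (0, 2)),
    ]
    fixed = []
    for pt, axes in targets:
        nid = int(np.argmin(np.linalg.norm(mesh.nodes - pt, axis=1)))
        if np.linalg.norm(mesh.nodes[nid] - pt) > 1e-6:
            raise RuntimeError(
                "no exact on-axis node; use an even n_surf for the shell"
            )
        for ax in axes:
            fixed.append((nid, ax, 0.0))
    return fixed


def solve_lame_sphere(
    a: float = 10.0, b: float = 20.0, p: float = 1.0,
    E: float = 10.0, nu: float = 0.3,
    n_surf: int = 6, n_rad: int = 4,
):
    """Solve the pressurized shell and return (rel L2 error, mesh, field).

    The fluid pressure acts on the inner surface: traction -p * n with n
    the solid's outward facet normal (which points into the cavity), i.e.
    the load pushes the shell outward.
    """
    mesh, inner, outer = spherical_shell_mesh(a, b, n_surf, n_rad)
    mats = MaterialParams(
        E={int(Tissue.FAT): E}, nu={int(Tissue.FAT): nu}, nu_cap=0.499
    )
    bcs = BoundaryConditions()
    for fi in inner:
        bcs.neumann[int(fi)] = ("pressure", -p)
    bcs.fixed_components = _axis_point_constraints(mesh, a)

    system = assemble(mesh, mats)
    fld = solve(system, bcs)

    r = np.linalg.norm(mesh.nodes, axis=1)
    u_exact = lame_radial_displacement(r, a, b, p, E, nu)
    rhat = mesh.nodes / r[:, None]
    u_exact_vec = u_exact[:, None] * rhat
    # volume-weighted (true L2) relative error via vertex quadrature
    vols = tet_volumes(mesh.nodes, mesh.tets)
    d2 = ((fld.u - u_exact_vec) ** 2).sum(axis=1)
    e2 = (u_exact_vec**2).sum(axis=1)
    num = (vols[:, None] / 4.0 * d2[mesh.tets]).sum()
    den = (vols[:, None] / 4.0 * e2[mesh.tets]).sum()
    return float(np.sqrt(num / den)), mesh, fld


def box_mesh(extent=(10.0, 10.0, 10.0), n=(4, 4, 4),
             label: int = int(Tissue.FAT)) -> TissueMesh:
    """Structured Freudenthal box mesh for patch tests and fixtures."""
    from .meshing import _CUBE_TETS

    ex = np.asarray(extent, dtype=float)
    nn = np.asarray(n, dtype=int)
    xs = [np.linspace(0, ex[d], nn[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    shape = grid.shape[:3]
    nodes = grid.reshape(-1, 3)

    def nid(i, j, k):
        return (i * shape[1] + j) * shape[2] + k

    cells = np.array([
        (i, j, k)
        for i in range(nn[0]) for j in range(nn[1]) for k in range(nn[2])
    ])
    offsets = np.array([[dx, dy, dz] for dz in (0, 1) for dy in (0, 1)
                        for dx in (0, 1)])
    corner = np.stack(
        [nid(cells[:, 0] + o[0], cells[:, 1] + o[1], cells[:, 2] + o[2])
         for o in offsets], axis=1,
    )
    tets = corner[:, _CUBE_TETS].reshape(-1, 4)
    vols = tet_volumes(nodes, tets)
    neg = np.flatnonzero(vols < 0)
    if len(neg):
        tets[np.ix_(neg, [2, 3])] = tets[np.ix_(neg, [3, 2])]

    boundary, _ = _boundary_facets(tets)
    from .meshing import _tag_facets

    tags = _tag_facets(nodes, boundary, None, float(ex[0] / nn[0]))
    return TissueMesh(
        nodes=nodes,
        tets=tets,
        tet_label=np.full(len(tets), int(label), dtype=np.int16),
        boundary_facets=boundary,
        facet_tags=tags,
        pitch=float(ex[0] / nn[0]),
    )
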