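"""Surgical plans and their compilation into boundary conditions.

Two scenarios are modeled.  RESECTION removes wall fragments: the opened
window becomes a traction boundary loaded by the intraorbital pressure,
except where the temporalis body sits directly outside the window — there
the herniating muscle blocks outflow and the facets stay fixed.
VALGIZATION (LAVA) keeps the lateral fragment: it is rigidly shifted along
its outward normal and rotated about a hinge on its anterior edge; soft
tissue in contact with the fragment follows it kinematically (step i), then
the opened window is pressurized on the updated geometry (step ii).
Because the fragment carries the temporalis outward with it, the valgized
window is never blocked.

The hinge placed on the anterior fragment edge (posterior edge swings
outward, expanding the deep/apex region) is a package choice — configurable
via the plan — as is the kinematic bone-tissue coupling through a contact
band with optional smooth edge blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .meshing import TissueMesh, facet_areas_normals
from .phantom import LabelVolume, Tissue, WallTag, WALL_SECTOR_TAGS

__all__ = [
    "WallFragment",
    "RigidTransform",
    "SurgicalPlan",
    "BoundaryConditions",
    "select_wall_fragment",
    "make_valgization",
    "compile_boundary_conditions",
]

RESECTION = "RESECTION"
VALGIZATION = "VALGIZATION"


class PlanError(ValueError):
    pass


@dataclass
class WallFragment:
    """A contiguous patch of tagged wall facets with a hinge on its
    anterior edge."""

    facet_ids: np.ndarray          # indices into mesh.boundary_facets
    wall_tag: int
    hinge_point: np.ndarray        # mm, on the anterior edge
    hinge_dir: np.ndarray          # unit vector
    outward_normal: np.ndarray     # area-weighted mean unit normal
    area_mm2: float

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / 100.0

    def node_ids(self, mesh: TissueMesh) -> np.ndarray:
        return np.unique(mesh.boundary_facets[self.facet_ids])


@dataclass(frozen=True)
class RigidTransform:
    """SE(3) transform stored as a 4x4 homogeneous matrix."""

    matrix: np.ndarray

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return p @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points) - np.atleast_2d(points)


@dataclass
class SurgicalPlan:
    """Scenario descriptor; serializable as YAML.

    ``wall_selections`` lists the fragments as (wall tag name, extent)
    pairs; extent may restrict the angular range (deg, phantom convention)
    and/or the axial range (mm).  Valgization transform parameters apply to
    the first selection.
    """

    scenario: str
    wall_selections: list = dc_field(default_factory=list)
    shift_mm: float = 0.0
    angle_deg: float = 0.0
    pressure_kpa: float = 0.0
    contact_tol_mm: float = 1.0
    blend_mm: float = 0.0
    release_mm: float = 0.0
    obstacle_probe_mm: float = 3.0
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        if self.scenario not in (RESECTION, VALGIZATION):
            raise PlanError(f"unknown scenario {self.scenario!r}")
        if self.shift_mm < 0:
            raise PlanError("shift must be >= 0")
        if not (0.0 <= self.angle_deg < 90.0):
            raise PlanError("valgization angle must lie in [0, 90) deg")
        if self.pressure_kpa < 0:
            raise PlanError("intraorbital pressure must be >= 0")
        if self.scenario == RESECTION and (self.shift_mm or self.angle_deg):
            raise PlanError("RESECTION plans carry no transform parameters")
        if not self.wall_selections:
            raise PlanError("plan needs at least one wall selection")

    def to_yaml(self, path) -> None:
        d = {
            "scenario": self.scenario,
            "wall_selections": [
                {"wall": WallTag(t).name, "extent": e or {}}
                for t, e in self._normalized_selections()
            ],
            "shift_mm": self.shift_mm,
            "angle_deg": self.angle_deg,
            "pressure_kpa": self.pressure_kpa,
            "contact_tol_mm": self.contact_tol_mm,
            "blend_mm": self.blend_mm,
            "name": self.name,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SurgicalPlan":
        d = yaml.safe_load(Path(path).read_text())
        sels = [
            (WallTag[s["wall"]], s.get("extent") or None)
            for s in d.pop("wall_selections")
        ]
        return cls(wall_selections=sels, **d)

    def _normalized_selections(self):
        out = []
        for sel in self.wall_selections:
            if isinstance(sel, (tuple, list)):
                tag, extent = sel
            else:
                tag, extent = sel, None
            out.append((WallTag(tag), extent))
        return out


@dataclass
class BoundaryConditions:
    """One simulation step's constraints and loads.

    ``dirichlet`` maps node -> prescribed displacement (mm).  ``neumann``
    maps boundary-facet index -> ("pressure", kPa) for a load following the
    current facet normal, or ("vector", traction kPa).  Nodes shared
    between a Dirichlet wall and a Neumann window edge stay Dirichlet;
    their traction contribution is dropped at solve time.
    ``fixed_components`` allows per-axis point constraints (node, axis,
    value) for benchmark problems.
    """

    dirichlet: dict = dc_field(default_factory=dict)
    neumann: dict = dc_field(default_factory=dict)
    body_force: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    fixed_components: list = dc_field(default_factory=list)

    def add_dirichlet(self, nodes, values) -> None:
        """Merge prescriptions; contradictory values are rejected."""
        values = np.atleast_2d(values)
        if len(values) == 1:
            values = np.repeat(values, len(nodes), axis=0)
        for n, v in zip(np.asarray(nodes, dtype=int), values):
            n = int(n)
            if n in self.dirichlet and not np.allclose(
                self.dirichlet[n], v, atol=1e-12
            ):
                raise PlanError(
                    f"conflicting Dirichlet prescriptions at node {n}"
                )
            self.dirichlet[n] = np.asarray(v, dtype=float)

    def dirichlet_arrays(self, n_nodes: int):
        """(3N,) fixed mask and values in dof ordering [n*3 + axis]."""
        fixed = np.zeros(3 * n_nodes, dtype=bool)
        vals = np.zeros(3 * n_nodes)
        for n, v in self.dirichlet.items():
            fixed[3 * n: 3 * n + 3] = True
            vals[3 * n: 3 * n + 3] = v
        for n, ax, val in self.fixed_components:
            fixed[3 * int(n) + int(ax)] = True
            vals[3 * int(n) + int(ax)] = val
        return fixed, vals


# ---------------------------------------------------------------------------

def select_wall_fragment(
    mesh: TissueMesh, wall_tag, extent_spec: dict | None = None
) -> WallFragment:
    """Select a contiguous facet patch on one wall sector.

    ``extent_spec`` may contain ``theta_range`` (deg, requires the phantom
    ground truth on the mesh) and/or ``y_range`` (mm); omitted keys mean
    the full sector.  Raises :class:`PlanError` on empty or edge-
    disconnected selections.
    """
    wall_tag = int(wall_tag)
    fidx = mesh.facets_with_tag(WallTag(wall_tag))
    if len(fidx) == 0:
        raise PlanError(f"wall tag {WallTag(wall_tag).name} absent from mesh boundary")
    cent = mesh.nodes[mesh.boundary_facets[fidx]].mean(axis=1)
    keep = np.ones(len(fidx), dtype=bool)
    if extent_spec:
        if "y_range" in extent_spec:
            lo, hi = extent_spec["y_range"]
            keep &= (cent[:, 1] >= lo) & (cent[:, 1] <= hi)
        if "theta_range" in extent_spec:
            gt = mesh.ground_truth
            if gt is None:
                raise PlanError("theta_range needs phantom ground truth on the mesh")
            lo, hi = extent_spec["theta_range"]
            th = np.degrees(np.arctan2(cent[:, 2] - gt.cavity.center_z,
                                       cent[:, 0] - gt.cavity.center_x))
            th = np.mod(th - lo, 360.0) + lo
            keep &= (th >= lo) & (th <= hi)
    fidx = fidx[keep]
    if len(fidx) == 0:
        raise PlanError("empty wall fragment selection")

    facets = mesh.boundary_facets[fidx]
    _check_contiguous(facets)

    areas, normals = facet_areas_normals(mesh.nodes, facets)
    mean_n = (normals * areas[:, None]).sum(axis=0)
    mean_n /= np.linalg.norm(mean_n)

    eff_areas = areas
    gt = mesh.ground_truth
    if gt is not None and wall_tag in [int(t) for t in WALL_SECTOR_TAGS]:
        # project residual voxel staircase onto the analytic wall surface:
        # the geometric wall area is the facet area times the cosine
        # between facet normal and the cone's outward surface normal
        cav = gt.cavity
        cent = mesh.nodes[facets].mean(axis=1)
        rho = np.hypot(cent[:, 0] - cav.center_x, cent[:, 2] - cav.center_z)
        cos_b = cav.depth / cav.slant_length
        sin_b = (cav.rim_radius - cav.apex_radius) / cav.slant_length
        with np.errstate(invalid="ignore"):
            radial = np.stack(
                [(cent[:, 0] - cav.center_x) / rho,
                 np.zeros(len(cent)),
                 (cent[:, 2] - cav.center_z) / rho], axis=1,
            )
        n_cone = radial * cos_b
        n_cone[:, 1] = -sin_b
        eff_areas = areas * np.abs((normals * n_cone).sum(axis=1))

    verts = np.unique(facets)
    p = mesh.nodes[verts]
    tol = max(mesh.pitch, 1e-6) * 1.01
    front = p[p[:, 1] >= p[:, 1].max() - tol]
    hinge_point = front.mean(axis=0)
    if len(front) >= 2:
        d = front - hinge_point
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        hinge_dir = vt[0]
    else:
        hinge_dir = np.array([0.0, 0.0, 1.0])
    # deterministic sign: prefer +z, then +x
    if hinge_dir[2] < 0 or (hinge_dir[2] == 0 and hinge_dir[0] < 0):
        hinge_dir = -hinge_dir
    hinge_dir = hinge_dir / np.linalg.norm(hinge_dir)

    return WallFragment(
        facet_ids=fidx,
        wall_tag=wall_tag,
        hinge_point=hinge_point,
        hinge_dir=hinge_dir,
        outward_normal=mean_n,
        area_mm2=float(eff_areas.sum()),
    )


def _check_contiguous(facets: np.ndarray) -> None:
    """Facets must form one vertex-connected component."""
    n = len(facets)
    if n == 1:
        return
    seen = {}
    rows, cols = [], []
    for i, f in enumerate(facets):
        for v in f:
            j = seen.setdefault(int(v), i)
            if j != i:
                rows.append(i)
                cols.append(j)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp > 1:
        raise PlanError(
            f"wall fragment selection is disconnected ({ncomp} components)"
        )


def make_valgization(
    fragment: WallFragment, shift_mm: float, angle_deg: float
) -> RigidTransform:
    """Rigid fragment motion: rotation about the hinge composed with a
    shift along the mean outward normal.

    The rotation sense is chosen so the fragment body swings outward
    (centroid displacement has a positive component along the outward
    normal); this is the valgus direction regardless of which orbit side
    the fragment sits on.
    """
    if shift_mm < 0 or not (0.0 <= angle_deg < 90.0):
        raise PlanError("invalid valgization parameters")
    axis = fragment.hinge_dir / np.linalg.norm(fragment.hinge_dir)
    p0 = fragment.hinge_point

    def rot(angle_rad):
        kx, ky, kz = axis
        K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K

    ang = np.radians(angle_deg)
    # test centroid displacement for both senses; outward wins
    c = p0 + 10.0 * np.array([0.0, -1.0, 0.0])  # posterior probe point
    best = None
    for sgn in (+1.0, -1.0):
        R = rot(sgn * ang)
        d = (R @ (c - p0) + p0) - c
        score = float(d @ fragment.outward_normal)
        if best is None or score > best[0]:
            best = (score, R)
    R = best[1] if angle_deg > 0 else np.eye(3)

    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = p0 - R @ p0 + shift_mm * fragment.outward_normal
    return RigidTransform(M)


# ---------------------------------------------------------------------------

def _facet_surface_samples(mesh: TissueMesh, facet_ids: np.ndarray) -> np.ndarray:
    f = mesh.boundary_facets[facet_ids]
    p = mesh.nodes[f]
    samples = [p.reshape(-1, 3), p.mean(axis=1)]
    for a, b in ((0, 1), (1, 2), (2, 0)):
        samples.append(0.5 * (p[:, a] + p[:, b]))
    return np.vstack(samples)


def _fragment_rim_samples(mesh: TissueMesh, facet_ids: np.ndarray) -> np.ndarray:
    """Points on edges the fragment shares with the rest of the boundary."""
    f = mesh.boundary_facets[facet_ids]
    cnt = {}
    for tri in f:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            cnt[key] = cnt.get(key, 0) + 1
    rim = [k for k, c in cnt.items() if c == 1]
    if not rim:
        return np.empty((0, 3))
    pts = []
    for a, b in rim:
        pa, pb = mesh.nodes[a], mesh.nodes[b]
        for t in (0.0, 0.5, 1.0):
            pts.append(pa + t * (pb - pa))
    return np.array(pts)


def compile_boundary_conditions(
    mesh: TissueMesh,
    plan: SurgicalPlan,
    obstacle: LabelVolume | None = None,
    transform_scale: float = 1.0,
) -> list[BoundaryConditions]:
    """Compile a plan into one (RESECTION) or two (VALGIZATION) steps.

    ``transform_scale`` in [0, 1] scales the valgization shift and angle —
    used by the incremental solver to follow the rotation arc.  The result
    is deterministic and idempotent for a given mesh/plan.
    """
    sels = plan._normalized_selections()
    fragments = [
        select_wall_fragment(mesh, tag, extent) for tag, extent in sels
    ]
    window = np.unique(np.concatenate([fr.facet_ids for fr in fragments]))
    window_set = set(window.tolist())

    wall_facets = np.concatenate(
        [mesh.facets_with_tag(t) for t in WALL_SECTOR_TAGS]
    )
    fixed_wall = np.array(
        [i for i in wall_facets if i not in window_set], dtype=int
    )
    apex = mesh.facets_with_tag(WallTag.APEX_FIXED)
    zero_sets = [fixed_wall, apex]

    bf = np.asarray(plan.body_force, dtype=float)

    if plan.scenario == RESECTION:
        open_f, blocked = _split_blocked(mesh, window, obstacle, plan)
        bc = BoundaryConditions(body_force=bf.copy())
        for fs in zero_sets + [blocked]:
            if len(fs):
                bc.add_dirichlet(
                    np.unique(mesh.boundary_facets[fs]), np.zeros(3)
                )
        for fi in open_f:
            # skip facets fully pinned by the fixed wall edge
            bc.neumann[int(fi)] = ("pressure", plan.pressure_kpa)
        return [bc]

    # VALGIZATION: fragment 0 carries the transform
    frag = fragments[0]
    s = float(np.clip(transform_scale, 0.0, 1.0))
    transform = make_valgization(frag, plan.shift_mm * s, plan.angle_deg * s)

    surf = _facet_surface_samples(mesh, frag.facet_ids)
    tree = cKDTree(surf)
    dist, _ = tree.query(mesh.nodes, k=1)
    near_frag = dist <= plan.contact_tol_mm

    # distance to the osteotomy cut (fragment rim) along the wall
    rim = _fragment_rim_samples(mesh, frag.facet_ids)
    if len(rim):
        rt = cKDTree(rim)
        drim, _ = rt.query(mesh.nodes, k=1)
    else:
        drim = np.full(mesh.n_nodes, np.inf)

    # tissue within release_mm of the cut is bonded to neither the
    # fragment nor the remaining wall (free); beyond it the contact band
    # follows the fragment, tapered over blend_mm.  When enabled, both
    # bands are widened to a minimum number of element layers so the free
    # ring survives coarsening.
    release = plan.release_mm
    if release > 0:
        release = max(release, 1.1 * mesh.pitch)
    blend = plan.blend_mm
    if blend > 0:
        blend = max(blend, 2.5 * mesh.pitch)
    released = drim < release
    w = np.ones(mesh.n_nodes)
    if blend > 0:
        w = np.clip((drim - release) / blend, 0.0, 1.0)
        w = w * w * (3.0 - 2.0 * w)  # smoothstep

    pinned = set()
    for fs in zero_sets:
        if len(fs):
            pinned.update(np.unique(mesh.boundary_facets[fs]).tolist())
    pinned -= set(np.flatnonzero(released).tolist())

    band = np.array(
        [n for n in np.flatnonzero(near_frag & ~released)
         if n not in pinned and w[n] > 0.0],
        dtype=int,
    )
    disp = transform.displacement(mesh.nodes[band]) * w[band, None]

    bc1 = BoundaryConditions(body_force=bf.copy())
    pinned_arr = np.array(sorted(pinned), dtype=int)
    if len(pinned_arr):
        bc1.add_dirichlet(pinned_arr, np.zeros(3))
    bc1.add_dirichlet(band, disp)

    # step (ii): nodes still in full contact with the displaced fragment
    # stay held; the opened gap along the cut (released ring + blend zone)
    # is pressurized through the facets that touch a free node.
    held = set(band[w[band] >= 0.999].tolist()) | pinned
    bc2 = BoundaryConditions(body_force=bf.copy())
    if len(pinned_arr):
        bc2.add_dirichlet(pinned_arr, np.zeros(3))
    held_band = np.array(sorted(set(band.tolist()) & held), dtype=int)
    if len(held_band):
        bc2.add_dirichlet(held_band, np.zeros(3))
    open_candidates = np.concatenate([frag.facet_ids, fixed_wall]) if len(
        fixed_wall) else frag.facet_ids
    for fi in open_candidates:
        tri = mesh.boundary_facets[int(fi)]
        if any(int(nd) not in held for nd in tri):
            bc2.neumann[int(fi)] = ("pressure", plan.pressure_kpa)
    return [bc1, bc2]


def _split_blocked(mesh, window, obstacle, plan):
    """Partition window facets into pressurized vs temporalis-blocked.

    A facet is blocked when a probe cast outward from its centroid lands
    in the temporalis body.  With phantom ground truth on the mesh the
    probe follows the analytic wall normal (the staircase facet normals
    scatter); several probe depths are tried so the bone shell thickness
    does not have to be known.
    """
    if obstacle is None:
        return window, np.array([], dtype=int)
    _, normals = facet_areas_normals(mesh.nodes, mesh.boundary_facets[window])
    cent = mesh.nodes[mesh.boundary_facets[window]].mean(axis=1)
    gt = mesh.ground_truth
    if gt is not None:
        cav = gt.cavity
        rho = np.hypot(cent[:, 0] - cav.center_x, cent[:, 2] - cav.center_z)
        cos_b = cav.depth / cav.slant_length
        sin_b = (cav.rim_radius - cav.apex_radius) / cav.slant_length
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.stack(
                [(cent[:, 0] - cav.center_x) / rho * cos_b,
                 np.full(len(cent), -sin_b),
                 (cent[:, 2] - cav.center_z) / rho * cos_b], axis=1,
            )
        normals[~np.isfinite(normals).all(axis=1)] = 0.0
    shape = obstacle.labels.shape
    blocked = np.zeros(len(window), dtype=bool)
    for depth in (plan.obstacle_probe_mm, plan.obstacle_probe_mm + 1.5,
                  plan.obstacle_probe_mm + 3.0):
        probe = cent + depth * normals
        idx = np.floor((probe - obstacle.origin) / obstacle.voxel_size).astype(int)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        lab = np.zeros(len(window), dtype=int)
        lab[inb] = obstacle.labels[tuple(idx[inb].T)]
        blocked |= lab == int(Tissue.TEMPORALIS)
    return window[~blocked], window[blocked]


def export_fragment_stl(mesh: TissueMesh, fragment: WallFragment,
                        transform: RigidTransform | None, path) -> None:
    """Write the (optionally displaced) fragment surface as ASCII STL."""
    import trimesh

    tris = mesh.boundary_facets[fragment.facet_ids]
    verts, inv = np.unique(tris, return_inverse=True)
    pts = mesh.nodes[verts]
    if transform is not None:
        pts = transform.apply(pts)
    tm = trimesh.Trimesh(pts, inv.reshape(-1, 3), process=False)
    Path(path).write_text(trimesh.exchange.stl.export_stl_ascii(tm))
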