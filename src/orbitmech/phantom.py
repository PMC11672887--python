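"""Parametric synthetic orbital phantom.

Generates a voxel labelmap emulating a segmented orbital CT: a truncated
bony cone (apex posterior, rim anterior) containing a spherical bulbus
(eyeball), rectus-like muscle bodies and fat filling the remaining cavity,
with a temporalis body hugging the lateral wall from outside.  Every tissue
is built from an analytic primitive, so exact volumes and wall-sector areas
are available as ground truth for downstream verification.

Coordinate convention (shared by the whole package): 0-based voxel indices;
world coordinates = origin + (index + 0.5) * voxel_size (voxel centers);
axes x = lateral, y = anterior, z = superior.  Units: mm.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Tissue",
    "WallTag",
    "PhantomSpec",
    "LabelVolume",
    "ConeFrustum",
    "PhantomGroundTruth",
    "generate_phantom",
    "load_labelmap",
    "save_labelmap",
]


class Tissue(IntEnum):
    """Voxel label codes of the segmentation."""

    BACKGROUND = 0
    BONE = 1
    FAT = 2
    MUSCLE = 3
    BULBUS = 4
    TEMPORALIS = 5


#: Tissues that deform elastically (bone and temporalis act only through
#: boundary conditions).
DEFORMABLE_TISSUES = (Tissue.FAT, Tissue.MUSCLE, Tissue.BULBUS)


class WallTag(IntEnum):
    """Boundary facet tags on the soft-tissue mesh."""

    LATERAL_WALL = 1
    FLOOR_WALL = 2
    MEDIAL_WALL = 3
    ROOF_WALL = 4
    APEX_FIXED = 5
    ANTERIOR_FREE = 6


WALL_SECTOR_TAGS = (
    WallTag.LATERAL_WALL,
    WallTag.FLOOR_WALL,
    WallTag.MEDIAL_WALL,
    WallTag.ROOF_WALL,
)


class GeometryError(ValueError):
    """A phantom specification violates one of its geometric invariants."""


@dataclass(frozen=True)
class ConeFrustum:
    """The bony orbital cavity: a truncated cone, apex posterior.

    The axis runs along +y from ``apex_y`` (radius ``apex_radius``) to
    ``apex_y + depth`` (radius ``rim_radius``), centered at ``(center_x,
    center_z)`` in the x-z plane.  Used as the "original cavity" descriptor
    when measuring released tissue volume.
    """

    center_x: float
    center_z: float
    apex_y: float
    depth: float
    apex_radius: float
    rim_radius: float

    @property
    def rim_y(self) -> float:
        return self.apex_y + self.depth

    @property
    def slant_length(self) -> float:
        dr = self.rim_radius - self.apex_radius
        return float(np.hypot(self.depth, dr))

    def radius_at(self, y):
        """Cavity radius at axial coordinate y (linear taper)."""
        t = (np.asarray(y) - self.apex_y) / self.depth
        return self.apex_radius + (self.rim_radius - self.apex_radius) * t

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the cavity (negative inside).

        Radial distance to the lateral cone surface scaled by cos(beta)
        (beta = surface-to-axis angle), combined with the two axial caps.
        Exact near the lateral surface, conservative near edges.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        rho = np.hypot(p[:, 0] - self.center_x, p[:, 2] - self.center_z)
        cos_beta = self.depth / self.slant_length
        d_lat = (rho - self.radius_at(p[:, 1])) * cos_beta
        d_apex = self.apex_y - p[:, 1]
        d_rim = p[:, 1] - self.rim_y
        return np.max(np.stack([d_lat, d_apex, d_rim]), axis=0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points) < 0.0

    @property
    def volume(self) -> float:
        """Frustum volume pi*h/3*(R^2 + R*r + r^2), mm^3."""
        R, r = self.rim_radius, self.apex_radius
        return float(np.pi * self.depth / 3.0 * (R * R + R * r + r * r))

    @property
    def lateral_area(self) -> float:
        """Full lateral (slant) surface area pi*(R+r)*s, mm^2."""
        return float(np.pi * (self.rim_radius + self.apex_radius) * self.slant_length)


def _default_wall_angles() -> dict[str, float]:
    # Lateral sector sized so its slant area is ~9.6 cm^2 under the default
    # cone (R=18, r=5, h=45); the remaining three sectors share the rest.
    return {"lateral": 102.1, "floor": 90.0, "medial": 80.0, "roof": 87.9}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic orbit.  All lengths in mm."""

    voxel_size: float = 1.0
    grid_shape: tuple[int, int, int] = (56, 64, 56)
    orbit_apex_depth: float = 45.0
    orbit_rim_radius: float = 18.0
    orbit_apex_radius: float = 5.0
    bulbus_radius: float = 11.0
    bulbus_center: tuple[float, float, float] | None = None
    muscle_count: int = 4
    muscle_radius: float = 2.5
    temporalis_offset: float = 6.0
    wall_thickness: float = 2.0
    wall_region_angles: dict[str, float] = field(default_factory=_default_wall_angles)
    seed: int = 0

    # derived placement ------------------------------------------------
    @property
    def center_xz(self) -> tuple[float, float]:
        nx, _, nz = self.grid_shape
        h = self.voxel_size
        return (nx * h / 2.0, nz * h / 2.0)

    @property
    def apex_y(self) -> float:
        return self.wall_thickness + 6.0

    @property
    def cavity(self) -> ConeFrustum:
        cx, cz = self.center_xz
        return ConeFrustum(
            center_x=cx,
            center_z=cz,
            apex_y=self.apex_y,
            depth=self.orbit_apex_depth,
            apex_radius=self.orbit_apex_radius,
            rim_radius=self.orbit_rim_radius,
        )

    def bulbus_center_world(self) -> np.ndarray:
        if self.bulbus_center is not None:
            return np.asarray(self.bulbus_center, dtype=float)
        cx, cz = self.center_xz
        cav = self.cavity
        return np.array([cx, cav.rim_y - self.bulbus_radius - 2.0, cz])

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise GeometryError("voxel_size must be > 0")
        for name in (
            "orbit_apex_depth",
            "orbit_rim_radius",
            "orbit_apex_radius",
            "bulbus_radius",
            "muscle_radius",
            "temporalis_offset",
            "wall_thickness",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.muscle_count < 0:
            raise GeometryError("muscle_count must be >= 0")
        if self.orbit_apex_radius >= self.orbit_rim_radius:
            raise GeometryError("orbit_apex_radius must be smaller than orbit_rim_radius")
        total = sum(self.wall_region_angles.values())
        if set(self.wall_region_angles) != {"lateral", "floor", "medial", "roof"}:
            raise GeometryError(
                "wall_region_angles must have exactly the keys lateral/floor/medial/roof"
            )
        if abs(total - 360.0) > 1e-6:
            raise GeometryError(
                f"wall sector angles must partition 360 deg (sum={total:g})"
            )
        cav = self.cavity
        c = self.bulbus_center_world()
        # bulbus strictly inside the cone: check the sphere's cross-section
        # radius against the cavity radius along its axial extent
        y_lo, y_hi = c[1] - self.bulbus_radius, c[1] + self.bulbus_radius
        if y_lo <= cav.apex_y or y_hi >= cav.rim_y:
            raise GeometryError(
                "bulbus must fit strictly inside the orbital cone "
                f"(axial extent [{y_lo:g}, {y_hi:g}] vs cavity "
                f"[{cav.apex_y:g}, {cav.rim_y:g}])"
            )
        ys = np.linspace(y_lo, y_hi, 64)
        cross = np.sqrt(np.maximum(self.bulbus_radius**2 - (ys - c[1]) ** 2, 0.0))
        rho_c = np.hypot(c[0] - cav.center_x, c[2] - cav.center_z)
        if np.any(rho_c + cross >= cav.radius_at(ys) - 0.25):
            raise GeometryError("bulbus must fit strictly inside the orbital cone")
        # grid large enough for orbit + bone + temporalis
        h = self.voxel_size
        ext = np.array(self.grid_shape, dtype=float) * h
        cx, cz = self.center_xz
        reach = self.orbit_rim_radius + self.wall_thickness + self.temporalis_offset
        if cx + reach > ext[0] or cz + reach > ext[2] or cx - reach < 0 or cz - reach < 0:
            raise GeometryError("grid too small to contain orbit plus temporalis body")
        if cav.rim_y + self.wall_thickness > ext[1]:
            raise GeometryError("grid too small along anterior axis")

    # sector helpers ---------------------------------------------------
    def sector_bounds(self) -> dict[str, tuple[float, float]]:
        """Angular intervals (degrees) per wall sector.

        Angle theta = atan2(z - cz, x - cx) in degrees, wrapped to
        [-180, 180); the lateral sector is centered on theta = 0 (+x), and
        the sectors proceed counter-clockwise lateral -> roof -> medial ->
        floor (roof at +z, medial at -x, floor at -z).
        """
        a = self.wall_region_angles
        start = -a["lateral"] / 2.0
        bounds = {}
        for name in ("lateral", "roof", "medial", "floor"):
            bounds[name] = (start, start + a[name])
            start += a[name]
        return bounds

    def sector_of(self, theta_deg: np.ndarray) -> np.ndarray:
        """Map angles (deg) to WallTag sector codes."""
        bounds = self.sector_bounds()
        start0 = bounds["lateral"][0]
        th = np.mod(np.asarray(theta_deg) - start0, 360.0) + start0
        out = np.full(th.shape, WallTag.LATERAL_WALL, dtype=np.int32)
        tags = {
            "lateral": WallTag.LATERAL_WALL,
            "floor": WallTag.FLOOR_WALL,
            "medial": WallTag.MEDIAL_WALL,
            "roof": WallTag.ROOF_WALL,
        }
        for name, (lo, hi) in bounds.items():
            m = (th >= lo) & (th < hi)
            out[m] = tags[name]
        return out

    # serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if self.bulbus_center is not None:
            d["bulbus_center"] = list(self.bulbus_center)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["grid_shape"] = tuple(d["grid_shape"])
        if d.get("bulbus_center") is not None:
            d["bulbus_center"] = tuple(d["bulbus_center"])
        return cls(**d)


@dataclass
class LabelVolume:
    """A 3D voxel labelmap with world placement."""

    labels: np.ndarray  # (nx, ny, nz) integer codes
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        codes = np.unique(self.labels)
        bad = set(codes.tolist()) - {int(t) for t in Tissue}
        if bad:
            raise ValueError(f"unknown label codes present: {sorted(bad)}")

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers (optionally masked)."""
        idx = np.argwhere(mask if mask is not None else np.ones(self.labels.shape, bool))
        return self.origin + (idx + 0.5) * self.voxel_size

    def tissue_volume(self, label: int) -> float:
        """Voxelized volume of one tissue, mm^3."""
        return float(np.count_nonzero(self.labels == int(label))) * self.voxel_size**3


@dataclass
class PhantomGroundTruth:
    """Analytic geometry the generator guarantees, for verification.

    ``volumes_mm3`` for fat/muscle/bulbus and the cavity are exact closed
    forms; bone and temporalis use offset-surface formulas that neglect end
    effects (stated accuracy ~5%).  ``sector_areas_mm2`` are exact conical
    frustum sector areas.
    """

    spec: PhantomSpec
    cavity: ConeFrustum
    volumes_mm3: dict[str, float]
    sector_areas_mm2: dict[str, float]

    @property
    def lateral_area_cm2(self) -> float:
        return self.sector_areas_mm2["lateral"] / 100.0


def _muscle_axial_range(spec: PhantomSpec) -> tuple[float, float]:
    """Axial span of the straight-in-y muscle tubes.

    Chosen so neighbouring tubes never overlap (centerline offset large
    enough) and tubes end 1 mm behind the bulbus posterior pole, keeping
    the tube volume an exact Cavalieri formula pi*r^2*L.
    """
    cav = spec.cavity
    margin = 0.8
    need = 2.0 * spec.muscle_radius / np.sqrt(2.0) + spec.muscle_radius + margin
    # offset(y) = rc(y) - muscle_radius - margin must exceed the pairwise
    # non-overlap bound; solve rc(y) >= need + muscle_radius + margin
    rc_min = need
    if cav.apex_radius >= rc_min:
        y0 = cav.apex_y + 1.0
    else:
        t = (rc_min - cav.apex_radius) / (cav.rim_radius - cav.apex_radius)
        y0 = cav.apex_y + t * cav.depth
    c = spec.bulbus_center_world()
    y1 = c[1] - spec.bulbus_radius - 1.0
    return float(y0), float(y1)


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomGroundTruth]:
    """Voxelize the parametric orbit into a labelmap + analytic ground truth.

    Deterministic for a fixed spec (the seed is carried for provenance and
    future stochastic extensions; the default generator is purely
    parametric).  Raises :class:`GeometryError` if the spec's invariants are
    violated.
    """
    spec.validate()
    h = spec.voxel_size
    nx, ny, nz = spec.grid_shape
    cav = spec.cavity
    cx, cz = cav.center_x, cav.center_z

    ix = (np.arange(nx) + 0.5) * h
    iy = (np.arange(ny) + 0.5) * h
    iz = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(ix, iy, iz, indexing="ij")

    rho = np.hypot(X - cx, Z - cz)
    t_ax = (Y - cav.apex_y) / cav.depth
    rc = cav.apex_radius + (cav.rim_radius - cav.apex_radius) * t_ax
    in_axial = (t_ax >= 0.0) & (t_ax <= 1.0)
    in_cavity = in_axial & (rho < rc)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[in_cavity] = Tissue.FAT

    # muscles: straight tubes along y at radial offset following the taper
    y0m, y1m = _muscle_axial_range(spec)
    if spec.muscle_count > 0 and y1m > y0m:
        in_mus_y = (Y >= y0m) & (Y <= y1m)
        off = rc - spec.muscle_radius - 0.8
        for k in range(spec.muscle_count):
            phi = 2.0 * np.pi * k / spec.muscle_count
            mx = cx + off * np.cos(phi)
            mz = cz + off * np.sin(phi)
            d2 = (X - mx) ** 2 + (Z - mz) ** 2
            m = in_cavity & in_mus_y & (d2 < spec.muscle_radius**2)
            labels[m] = Tissue.MUSCLE

    # bulbus sphere
    c = spec.bulbus_center_world()
    d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
    labels[in_cavity & (d2 < spec.bulbus_radius**2)] = Tissue.BULBUS

    # bone: conical shell + apex cap + anterior lid (orbital rim/septum)
    cos_beta = cav.depth / cav.slant_length
    dn = (rho - rc) * cos_beta  # normal distance to lateral surface
    shell = in_axial & (dn >= 0.0) & (dn < spec.wall_thickness)
    cap_apex = (Y < cav.apex_y) & (Y >= cav.apex_y - spec.wall_thickness) & (
        rho < cav.apex_radius + spec.wall_thickness
    )
    cap_rim = (Y >= cav.rim_y) & (Y < cav.rim_y + spec.wall_thickness) & (
        rho < cav.rim_radius + spec.wall_thickness
    )
    labels[shell | cap_apex | cap_rim] = Tissue.BONE

    # temporalis: a shell sector outside the lateral bone wall
    theta = np.degrees(np.arctan2(Z - cz, X - cx))
    lat_lo, lat_hi = spec.sector_bounds()["lateral"]
    th = np.mod(theta - lat_lo, 360.0) + lat_lo
    in_lat = (th >= lat_lo) & (th < lat_hi)
    temp = (
        in_axial
        & in_lat
        & (dn >= spec.wall_thickness)
        & (dn < spec.wall_thickness + spec.temporalis_offset)
        & (t_ax >= 0.08)
    )
    labels[temp & (labels == Tissue.BACKGROUND)] = Tissue.TEMPORALIS

    volume = LabelVolume(labels=labels, voxel_size=h, origin=np.zeros(3))

    # ---- analytic ground truth ----
    v_cavity = cav.volume
    v_bulbus = 4.0 / 3.0 * np.pi * spec.bulbus_radius**3
    v_muscle = (
        spec.muscle_count * np.pi * spec.muscle_radius**2 * max(y1m - y0m, 0.0)
    )
    v_fat = v_cavity - v_bulbus - v_muscle
    s = cav.slant_length
    R, r = cav.rim_radius, cav.apex_radius
    tw = spec.wall_thickness
    # shell between offset cones: V = pi*s*[(R+r)*T + cos(beta)*T^2], ~5%
    v_bone = np.pi * s * ((R + r) * tw + cos_beta * tw * tw)
    v_bone += np.pi * (r + tw) ** 2 * tw + np.pi * (R + tw) ** 2 * tw  # caps
    frac_lat = spec.wall_region_angles["lateral"] / 360.0
    to = spec.temporalis_offset
    v_temp = frac_lat * np.pi * s * (
        (R + r) * to + cos_beta * ((tw + to) ** 2 - tw**2)
    ) * 0.92  # axial trim t>=0.08

    areas = {
        name: cav.lateral_area * ang / 360.0
        for name, ang in spec.wall_region_angles.items()
    }
    gt = PhantomGroundTruth(
        spec=spec,
        cavity=cav,
        volumes_mm3={
            "cavity": v_cavity,
            "fat": v_fat,
            "muscle": v_muscle,
            "bulbus": v_bulbus,
            "bone": float(v_bone),
            "temporalis": float(v_temp),
        },
        sector_areas_mm2=areas,
    )
    return volume, gt


# ---------------------------------------------------------------------------
# labelmap I/O (NIfTI-1)

def save_labelmap(volume: LabelVolume, path) -> None:
    """Write a labelmap as NIfTI-1 with voxel size and origin in the affine."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = volume.voxel_size
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def load_labelmap(path) -> LabelVolume:
    """Load a NIfTI labelmap; validates label codes, warns if empty."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("labelmap voxel values must be integers")
        data = np.round(data).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], atol=1e-6):
        raise ValueError("anisotropic voxels are not supported")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    vol = LabelVolume(labels=data.astype(np.int16), voxel_size=float(zooms[0]),
                      origin=origin)
    if not np.any(np.isin(vol.labels, [int(t) for t in DEFORMABLE_TISSUES])):
        warnings.warn("no tissue labels present in labelmap", stacklevel=2)
    return vol
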