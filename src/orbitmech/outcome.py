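"""Outcome quantification for decompression scenarios.

The central quantity is the released intraorbital tissue volume: the volume
of deformed soft tissue lying outside the original bony cavity.  It is
computed by high-resolution voxelization of the deformed tetrahedra against
the analytic cavity descriptor ("voxel" mode); a boundary-flux
approximation of the same quantity (outward normal flux of the displacement
over the original cavity surface, "flux" mode) serves as a fast
cross-check.  Reports follow the area / volume / volume-per-area layout the
scenarios are compared in, in cm^2 and cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elasticity import DisplacementField, ScenarioResult
from .meshing import TissueMesh, facet_areas_normals
from .phantom import ConeFrustum, Tissue
from .surgery import SurgicalPlan, select_wall_fragment

__all__ = [
    "OutcomeReport",
    "released_volume",
    "proptosis_change",
    "compute_outcome",
    "compare_scenarios",
]


@dataclass
class OutcomeReport:
    """Per-scenario outcome in report units (cm^2, cm^3, mm)."""

    scenario: str
    area_cm2: float
    released_cm3: float
    proptosis_mm: float
    per_tissue_cm3: dict = field(default_factory=dict)
    method: str = "voxel"
    resolution_mm: float = 0.5

    def __post_init__(self):
        if self.area_cm2 <= 0:
            raise ValueError("affected area must be > 0")
        if self.released_cm3 < -1e-9:
            raise ValueError("released volume must be >= 0")
        self.released_cm3 = max(self.released_cm3, 0.0)

    @property
    def volume_per_area(self) -> float:
        """Released volume per affected area, cm^3/cm^2 (= cm)."""
        return self.released_cm3 / self.area_cm2

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "area_cm2": self.area_cm2,
            "released_cm3": self.released_cm3,
            "volume_per_area": self.volume_per_area,
            "proptosis_mm": self.proptosis_mm,
            "per_tissue_cm3": dict(self.per_tissue_cm3),
            "method": self.method,
            "resolution_mm": self.resolution_mm,
        }


def _rasterize_occupancy(
    nodes: np.ndarray,
    tets: np.ndarray,
    lo: np.ndarray,
    dims: np.ndarray,
    resolution: float,
) -> np.ndarray:
    """Boolean lattice occupancy of the tet union (voxel-center sampling)."""
    occupied = np.zeros(tuple(dims), dtype=bool)
    p = nodes[tets]
    M = p[:, 1:] - p[:, :1]
    Minv = np.linalg.inv(M)

    for i in range(len(tets)):
        pmin = p[i].min(axis=0)
        pmax = p[i].max(axis=0)
        i0 = np.maximum(((pmin - lo) / resolution - 0.5).astype(int), 0)
        i1 = np.minimum(
            ((pmax - lo) / resolution + 0.5).astype(int) + 1, dims
        )
        if np.any(i0 >= i1):
            continue
        gx = lo[0] + (np.arange(i0[0], i1[0]) + 0.5) * resolution
        gy = lo[1] + (np.arange(i0[1], i1[1]) + 0.5) * resolution
        gz = lo[2] + (np.arange(i0[2], i1[2]) + 0.5) * resolution
        X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
        # rows of M are edge vectors, so x - p0 = lam @ M
        pts = np.stack([X, Y, Z], axis=-1) - p[i, 0]
        lam = pts @ Minv[i]
        inside = (
            (lam >= -1e-12).all(axis=-1) & (lam.sum(axis=-1) <= 1.0 + 1e-12)
        )
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    return occupied


def released_volume(
    mesh: TissueMesh,
    field: DisplacementField,
    cavity: ConeFrustum | None = None,
    resolution_mm: float = 0.5,
    method: str = "voxel",
    labels=None,
) -> float:
    """Deformed-tissue volume outside the original bony cavity, cm^3.

    ``method="voxel"`` rasterizes the deformed and the undeformed tets on
    a shared lattice of pitch ``resolution_mm`` and counts lattice points
    that are outside the cavity, covered by the deformed tissue and not
    covered by the undeformed tissue — newly occupied extra-cavity space.
    Referencing the undeformed occupancy makes a zero field measure
    exactly zero even though the discrete mesh boundary only approximates
    the cavity surface.  ``method="flux"`` integrates the outward normal
    displacement over the original boundary (first-order, fast; counts
    only outward motion).
    """
    if len(field.u) != mesh.n_nodes:
        raise ValueError("displacement field does not match mesh")
    if cavity is None:
        if mesh.ground_truth is None:
            raise ValueError("no cavity descriptor available")
        cavity = mesh.ground_truth.cavity

    if labels is None:
        sel = np.ones(mesh.n_tets, dtype=bool)
    else:
        sel = np.isin(mesh.tet_label, [int(l) for l in np.atleast_1d(labels)])

    if method == "flux":
        areas, normals = facet_areas_normals(mesh.nodes, mesh.boundary_facets)
        ubar = field.u[mesh.boundary_facets].mean(axis=1)
        un = (ubar * normals).sum(axis=1)
        return float(np.maximum(un, 0.0) @ areas) / 1000.0
    if method != "voxel":
        raise ValueError(f"unknown method {method!r}")

    deformed = mesh.nodes + field.u
    lo = np.minimum(deformed.min(axis=0), mesh.nodes.min(axis=0)) - resolution_mm
    hi = np.maximum(deformed.max(axis=0), mesh.nodes.max(axis=0)) + resolution_mm
    dims = np.maximum(np.ceil((hi - lo) / resolution_mm).astype(int), 1)
    occ_def = _rasterize_occupancy(deformed, mesh.tets[sel], lo, dims,
                                   resolution_mm)
    occ_ref = _rasterize_occupancy(mesh.nodes, mesh.tets[sel], lo, dims,
                                   resolution_mm)
    new = occ_def & ~occ_ref
    idx = np.argwhere(new)
    if len(idx) == 0:
        return 0.0
    centers = lo + (idx + 0.5) * resolution_mm
    out = int(np.count_nonzero(cavity.signed_distance(centers) > 1e-9))
    return out * resolution_mm**3 / 1000.0


def proptosis_change(mesh: TissueMesh, field: DisplacementField) -> float:
    """Recession of the bulbus front pole along the anterior (+y) axis, mm.

    Positive values mean the eyeball recedes posteriorly after surgery.
    """
    bulbus = mesh.tet_label == int(Tissue.BULBUS)
    if not bulbus.any():
        raise ValueError("mesh has no bulbus tets")
    nodes = np.unique(mesh.tets[bulbus])
    y0 = mesh.nodes[nodes, 1].max()
    y1 = (mesh.nodes[nodes, 1] + field.u[nodes, 1]).max()
    return float(y0 - y1)


def compute_outcome(
    mesh: TissueMesh,
    result: ScenarioResult,
    resolution_mm: float = 0.5,
    method: str = "voxel",
) -> OutcomeReport:
    """Assemble the outcome report for one simulated scenario."""
    plan: SurgicalPlan = result.plan
    area = sum(
        select_wall_fragment(mesh, tag, ext).area_mm2
        for tag, ext in plan._normalized_selections()
    ) / 100.0
    per_tissue = {}
    for lbl in (Tissue.FAT, Tissue.MUSCLE, Tissue.BULBUS):
        if np.any(mesh.tet_label == int(lbl)):
            per_tissue[lbl.name.lower()] = released_volume(
                mesh, result.field, resolution_mm=resolution_mm,
                method=method, labels=[lbl],
            )
    total = released_volume(
        mesh, result.field, resolution_mm=resolution_mm, method=method
    )
    return OutcomeReport(
        scenario=plan.name or plan.scenario,
        area_cm2=area,
        released_cm3=total,
        proptosis_mm=proptosis_change(mesh, result.field),
        per_tissue_cm3=per_tissue,
        method=method,
        resolution_mm=resolution_mm,
    )


def compare_scenarios(reports: list[OutcomeReport]) -> pd.DataFrame:
    """Tabulate scenarios plus pairwise volume-per-area ratio-of-ratios.

    Row i, column ``ratio_vs_<j>`` holds (V/A)_i / (V/A)_j.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for r in reports:
        rows.append(
            {
                "scenario": r.scenario,
                "area_cm2": r.area_cm2,
                "released_cm3": r.released_cm3,
                "volume_per_area": r.volume_per_area,
                "proptosis_mm": r.proptosis_mm,
            }
        )
    df = pd.DataFrame(rows)
    for j, rj in enumerate(reports):
        df[f"ratio_vs_{rj.scenario}"] = [
            r.volume_per_area / rj.volume_per_area if rj.volume_per_area else np.nan
            for r in reports
        ]
    return df


def comparison_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.4f}")
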