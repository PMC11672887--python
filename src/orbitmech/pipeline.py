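"""End-to-end pipeline: phantom -> mesh -> scenarios -> outcome reports.

``run_pipeline`` is deterministic for a fixed config and seed, and writes
all artifacts (NIfTI labelmap, VTU meshes and fields, CSV/JSON reports,
run log) under the configured output directory with byte-stable content.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .elasticity import MaterialParams, simulate_scenario
from .io_formats import write_vtu
from .meshing import build_tet_mesh, mesh_quality
from .outcome import OutcomeReport, compare_scenarios, comparison_text, compute_outcome
from .phantom import PhantomSpec, Tissue, generate_phantom, load_labelmap, save_labelmap
from .surgery import SurgicalPlan, WallTag

__all__ = ["RunConfig", "run_pipeline", "default_lava_plan",
           "default_twowall_plan", "default_config"]


def default_lava_plan(pressure_kpa: float = 0.2) -> SurgicalPlan:
    """LAVA: valgize the full lateral-wall fragment, 2.5 mm shift + 30 deg
    hinge rotation, then pressurized outflow through the opened window."""
    return SurgicalPlan(
        scenario="VALGIZATION",
        wall_selections=[(WallTag.LATERAL_WALL, None)],
        shift_mm=2.5,
        angle_deg=30.0,
        pressure_kpa=pressure_kpa,
        contact_tol_mm=1.0,
        blend_mm=8.0,
        release_mm=3.0,
        name="LAVA",
    )


def default_twowall_plan(pressure_kpa: float = 0.2) -> SurgicalPlan:
    """Two-wall resection: open the lateral and floor wall fragments and
    let the fat flow out under uniform intraorbital pressure (the lateral
    window is blocked wherever the temporalis sits behind it)."""
    return SurgicalPlan(
        scenario="RESECTION",
        wall_selections=[(WallTag.LATERAL_WALL, None), (WallTag.FLOOR_WALL, None)],
        pressure_kpa=pressure_kpa,
        name="two-wall",
    )


@dataclass
class RunConfig:
    phantom_spec: PhantomSpec | str = field(default_factory=PhantomSpec)
    labelmap_path: str | None = None
    plans: list = field(default_factory=lambda: [default_lava_plan(),
                                                 default_twowall_plan()])
    materials: MaterialParams = field(
        default_factory=MaterialParams.orbital_defaults
    )
    target_edge_mm: float = 2.0
    n_steps: int = 10
    contact_tol_factor: float | None = None
    outcome_resolution_mm: float = 0.75
    outcome_method: str = "voxel"
    out_dir: str = "orbitmech_out"
    seed: int = 0
    write_vtu: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        kw = {}
        if "phantom_spec" in d:
            v = d["phantom_spec"]
            kw["phantom_spec"] = (
                PhantomSpec.from_yaml(v) if isinstance(v, str) else _spec_from_dict(v)
            )
        if "plans" in d:
            kw["plans"] = [
                SurgicalPlan.from_yaml(p) if isinstance(p, str) else _plan_from_dict(p)
                for p in d["plans"]
            ]
        if "materials" in d:
            m = d["materials"]
            kw["materials"] = MaterialParams.orbital_defaults(**m)
        for k in ("labelmap_path", "target_edge_mm", "n_steps",
                  "outcome_resolution_mm", "outcome_method", "out_dir",
                  "seed", "write_vtu"):
            if k in d:
                kw[k] = d[k]
        return cls(**kw)


def _spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if "grid_shape" in d:
        d["grid_shape"] = tuple(d["grid_shape"])
    return PhantomSpec(**d)


def _plan_from_dict(d: dict) -> SurgicalPlan:
    d = dict(d)
    sels = [
        (WallTag[s["wall"]], s.get("extent") or None)
        for s in d.pop("wall_selections")
    ]
    return SurgicalPlan(wall_selections=sels, **d)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def run_pipeline(config: RunConfig) -> list[OutcomeReport]:
    """Run every configured scenario and write reports + artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"orbitmech {__version__} on python {platform.python_version()}",
        f"seed {config.seed}",
    ]

    if config.labelmap_path:
        volume = load_labelmap(config.labelmap_path)
        gt = None
        log_lines.append(f"labelmap loaded from {config.labelmap_path}")
    else:
        spec = config.phantom_spec
        if isinstance(spec, str):
            spec = PhantomSpec.from_yaml(spec)
        spec = dataclasses.replace(spec, seed=config.seed)
        volume, gt = generate_phantom(spec)
        save_labelmap(volume, out / "phantom.nii.gz")
        log_lines.append(
            "phantom generated: grid "
            + "x".join(map(str, spec.grid_shape))
            + f" at {spec.voxel_size} mm"
        )

    mesh = build_tet_mesh(volume, target_edge=config.target_edge_mm,
                          ground_truth=gt)
    q = mesh_quality(mesh)
    if q.inverted_count:
        raise RuntimeError(f"stage mesh: {q.inverted_count} inverted tets")
    log_lines.append(
        f"mesh: {q.n_nodes} nodes, {q.n_tets} tets, "
        f"min dihedral {q.min_dihedral_deg:.1f} deg, "
        f"max aspect {q.max_aspect:.2f}"
    )
    if config.write_vtu:
        write_vtu(out / "mesh.vtu", mesh)

    reports = []
    for plan in config.plans:
        try:
            res = simulate_scenario(
                mesh, plan, config.materials, n_steps=config.n_steps,
                obstacle=volume,
            )
            rep = compute_outcome(
                mesh, res, resolution_mm=config.outcome_resolution_mm,
                method=config.outcome_method,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage simulate[{plan.name or plan.scenario}]: {exc}"
            ) from exc
        reports.append(rep)
        name = (plan.name or plan.scenario).replace(" ", "_")
        (out / f"report_{name}.json").write_text(
            json.dumps(rep.to_dict(), indent=2, sort_keys=True,
                       default=_json_default)
            + "\n"
        )
        if config.write_vtu:
            sd = mesh.ground_truth.cavity.signed_distance(
                mesh.nodes + res.field.u
            ) if mesh.ground_truth is not None else np.zeros(mesh.n_nodes)
            write_vtu(
                out / f"field_{name}.vtu", mesh,
                nodes=mesh.nodes + res.field.u,
                point_data={
                    "displacement": res.field.u,
                    "outside_original_cavity": (sd > 0).astype(float),
                },
            )
        log_lines.append(
            f"scenario {rep.scenario}: area {rep.area_cm2:.2f} cm2, "
            f"released {rep.released_cm3:.3f} cm3, "
            f"V/A {rep.volume_per_area:.4f} cm"
        )

    if len(reports) >= 2:
        df = compare_scenarios(reports)
        df.to_csv(out / "comparison.csv", index=False,
                  float_format="%.6f")
        (out / "comparison.txt").write_text(comparison_text(df) + "\n")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return reports


def default_config(out_dir: str = "orbitmech_out", **kw) -> RunConfig:
    return RunConfig(out_dir=out_dir, **kw)
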