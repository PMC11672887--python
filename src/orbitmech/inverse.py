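"""Inverse estimation of tissue parameters from observed outcome.

Linear elasticity with traction loading has an exact scale degeneracy: the
displacement field depends on the loads and moduli only through their
ratios.  Fitting absolute Young's moduli together with the effective
intraorbital pressure is therefore ill-posed, and this module makes the
degeneracy explicit: the identifiable coordinates are the
pressure-to-fat-stiffness ratio ``p_over_e_fat``, the muscle-to-fat
stiffness ratio ``e_muscle_ratio`` and the Poisson ratio ``nu``; a request
to fit ``e_fat`` and ``pressure`` jointly is refused.  The optimizer is a
bound-projected Nelder–Mead simplex with seeded random restarts, as the
objective is a black-box simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .elasticity import MaterialParams, simulate_scenario
from .meshing import TissueMesh
from .outcome import released_volume
from .phantom import Tissue
from .surgery import SurgicalPlan

__all__ = [
    "ObservedOutcome",
    "FitResult",
    "IdentifiabilityError",
    "canonical_params",
    "objective",
    "fit_parameters",
]

BULBUS_RATIO_FIXED = 30.0  # globe stiffness ratio held fixed during fitting


class IdentifiabilityError(ValueError):
    pass


@dataclass
class ObservedOutcome:
    """Observed post-surgery outcome: a released volume and/or sparse
    surface displacement samples (point mm, displacement mm)."""

    released_cm3: float | None = None
    sample_points: np.ndarray | None = None
    sample_disp: np.ndarray | None = None
    noise_level: float = 0.0

    def __post_init__(self):
        has_disp = self.sample_points is not None and len(self.sample_points)
        if self.released_cm3 is None and not has_disp:
            raise ValueError("at least one observation is required")
        if has_disp:
            self.sample_points = np.asarray(self.sample_points, dtype=float)
            self.sample_disp = np.asarray(self.sample_disp, dtype=float)
            if self.sample_disp.shape != self.sample_points.shape:
                raise ValueError("sample point/displacement shape mismatch")


@dataclass
class FitResult:
    params: dict
    objective_value: float
    trajectory: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def canonical_params(params: dict) -> dict:
    """Reduce a parameter dict to identifiable coordinates.

    Accepts either ``p_over_e_fat`` directly or the absolute pair
    ``e_fat`` + ``pressure`` (collapsed to their ratio, which is all the
    traction-driven linear model can see).
    """
    p = dict(params)
    if "p_over_e_fat" not in p:
        if "e_fat" in p and "pressure" in p:
            p["p_over_e_fat"] = p.pop("pressure") / p.pop("e_fat")
        else:
            raise ValueError(
                "parameters must provide p_over_e_fat or (e_fat, pressure)"
            )
    else:
        p.pop("e_fat", None)
        p.pop("pressure", None)
    p.setdefault("e_muscle_ratio", 4.0)
    p.setdefault("nu", 0.45)
    if p["p_over_e_fat"] <= 0 or p["e_muscle_ratio"] <= 0:
        raise ValueError("ratios must be positive")
    if not (0.0 <= p["nu"] <= 0.5):
        raise ValueError("nu must lie in [0, 0.5]")
    return {k: float(p[k]) for k in ("p_over_e_fat", "e_muscle_ratio", "nu")}


class ForwardModel:
    """Simulate a plan for given identifiable parameters and extract the
    observables (released volume + displacement at sample points)."""

    def __init__(
        self,
        mesh: TissueMesh,
        plan: SurgicalPlan,
        obstacle=None,
        n_steps: int = 1,
        volume_method: str = "flux",
        sample_points: np.ndarray | None = None,
    ):
        self.mesh = mesh
        self.plan = plan
        self.obstacle = obstacle
        self.n_steps = n_steps
        self.volume_method = volume_method
        self._sample_nodes = None
        if sample_points is not None and len(sample_points):
            tree = cKDTree(mesh.nodes)
            _, self._sample_nodes = tree.query(
                np.asarray(sample_points, dtype=float), k=1
            )

    def predict(self, params: dict):
        c = canonical_params(params)
        e_fat = 1.0  # reference scale; only ratios matter
        mats = MaterialParams.orbital_defaults(
            e_fat=e_fat,
            muscle_ratio=c["e_muscle_ratio"],
            bulbus_ratio=BULBUS_RATIO_FIXED,
            nu=c["nu"],
        )
        import dataclasses as _dc

        plan = _dc.replace(self.plan, pressure_kpa=c["p_over_e_fat"] * e_fat)
        res = simulate_scenario(
            self.mesh, plan, mats, n_steps=self.n_steps, obstacle=self.obstacle
        )
        vol = released_volume(
            self.mesh, res.field, method=self.volume_method
        )
        disp = (
            res.field.u[self._sample_nodes]
            if self._sample_nodes is not None
            else None
        )
        return vol, disp

    def synthesize_observation(
        self, params: dict, noise_level: float = 0.0, rng=None
    ) -> ObservedOutcome:
        """Generate a (possibly noisy) observation at known parameters."""
        vol, disp = self.predict(params)
        pts = (
            self.mesh.nodes[self._sample_nodes]
            if self._sample_nodes is not None
            else None
        )
        if noise_level > 0:
            rng = np.random.default_rng(rng)
            vol = vol * (1.0 + noise_level * rng.standard_normal())
            if disp is not None:
                disp = disp * (
                    1.0 + noise_level * rng.standard_normal(disp.shape)
                )
        return ObservedOutcome(
            released_cm3=vol,
            sample_points=pts,
            sample_disp=disp,
            noise_level=noise_level,
        )


def objective(
    params: dict,
    observed: ObservedOutcome,
    mesh: TissueMesh,
    plan: SurgicalPlan,
    forward: ForwardModel | None = None,
    weight_volume: float = 1.0,
    weight_disp: float = 1.0,
) -> float:
    """Weighted sum of squared normalized discrepancies; zero iff the
    simulation reproduces every observation."""
    if forward is None:
        forward = ForwardModel(
            mesh, plan, sample_points=observed.sample_points
        )
    vol, disp = forward.predict(params)
    obj = 0.0
    if observed.released_cm3 is not None:
        scale = max(abs(observed.released_cm3), 1e-6)
        obj += weight_volume * ((vol - observed.released_cm3) / scale) ** 2
    if observed.sample_disp is not None and disp is not None:
        scale = max(float(np.linalg.norm(observed.sample_disp)), 1e-9)
        obj += weight_disp * float(
            np.sum((disp - observed.sample_disp) ** 2)
        ) / scale**2
    return float(obj)


_DEFAULT_BOUNDS = {
    "p_over_e_fat": (1e-3, 10.0),
    "e_muscle_ratio": (0.1, 100.0),
    "nu": (0.0, 0.49),
}


def fit_parameters(
    observed: ObservedOutcome,
    mesh: TissueMesh,
    plan: SurgicalPlan,
    init: dict,
    bounds: dict | None = None,
    seed: int = 17,
    restarts: int = 3,
    maxiter: int = 200,
    obstacle=None,
    n_steps: int = 1,
) -> FitResult:
    """Derivative-free recovery of the identifiable parameters.

    ``init`` names the free parameters (any subset of p_over_e_fat,
    e_muscle_ratio, nu) with their starting values; requesting absolute
    ``e_fat`` and ``pressure`` jointly raises
    :class:`IdentifiabilityError`.  Deterministic given init and seed.
    """
    free = list(init)
    if "e_fat" in free and "pressure" in free:
        raise IdentifiabilityError(
            "absolute E_fat and pressure cannot be fit jointly: traction-"
            "driven linear elasticity determines only their ratio; fit "
            "p_over_e_fat instead"
        )
    unknown = [k for k in free if k not in _DEFAULT_BOUNDS]
    if unknown:
        raise IdentifiabilityError(f"unsupported free parameters: {unknown}")
    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    forward = ForwardModel(
        mesh, plan, obstacle=obstacle, n_steps=n_steps,
        sample_points=observed.sample_points,
    )

    log_scale = {"p_over_e_fat", "e_muscle_ratio"}

    def to_z(p):
        return np.array(
            [np.log(p[k]) if k in log_scale else p[k] for k in free]
        )

    def from_z(z):
        p = dict(init)
        for k, zk in zip(free, z):
            v = float(np.exp(zk)) if k in log_scale else float(zk)
            lo, hi = bnds[k]
            p[k] = min(max(v, lo), hi)
        return p

    trajectory = []
    best = [np.inf, None]

    def fun(z):
        p = from_z(z)
        val = objective(p, observed, mesh, plan, forward=forward)
        if val < best[0]:
            best[0], best[1] = val, p
        trajectory.append(best[0])
        return val

    rng = np.random.default_rng(seed)
    z0 = to_z({k: float(init[k]) for k in free})
    starts = [z0]
    for _ in range(max(restarts - 1, 0)):
        starts.append(z0 + 0.25 * rng.standard_normal(len(z0)))

    n_iter = 0
    converged = False
    tol = 1e-10
    # fixed-point fast path: an init that already reproduces the
    # observations needs no simplex search
    if fun(z0) <= tol:
        return FitResult(
            params=best[1], objective_value=best[0], trajectory=trajectory,
            converged=True, n_iter=1,
        )
    for zs in starts:
        res = minimize(
            fun, zs, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12},
        )
        n_iter += int(res.nit)
        if res.success or best[0] < tol:
            converged = True
        if best[0] < tol:
            break

    # relative-improvement convergence check over the trailing window
    if len(trajectory) > 20:
        a, b = trajectory[-21], trajectory[-1]
        if a > 0 and (a - b) / a < 1e-6:
            converged = True

    return FitResult(
        params=best[1],
        objective_value=best[0],
        trajectory=trajectory,
        converged=converged,
        n_iter=n_iter,
    )
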