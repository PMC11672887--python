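# orbitmech

Finite-element simulation of orbital decompression surgery for thyroid
eye disease (TED), comparing **lateral wall valgization (LAVA)** — a
hinged outward rotation of an intact lateral-wall fragment — with
conventional **wall resection**.

In TED, swollen intraorbital fat and muscle push the eyeball forward
(exophthalmos).  Decompression surgery removes or displaces bony orbital
walls so the pressurized soft tissue can expand outward.  Resecting the
lateral wall has a known failure mode: the temporalis muscle herniates
into the defect and re-closes the decompressed space.  Valgization
instead swings the intact fragment outward about a hinge, relocating the
temporalis with it and keeping the new lateral space open.  `orbitmech`
quantifies that difference mechanically: it predicts the **released
intraorbital tissue volume** — deformed tissue ending up outside the
original bony cavity — per unit of affected wall area, for both
strategies, on a fully synthetic orbit model with exact analytic ground
truth (no patient data required).

## The model

Soft tissue (fat, muscle, eyeball) is an isotropic, piecewise linear
elastic (Hookean) material.  The displacement u under loads f solves the
Lamé–Navier equations of linear elastostatics,

    Δu + (1 − 2ν)⁻¹ grad div u = −2(1 + ν) E⁻¹ f,

discretized with linear tetrahedra on a labeled mesh built from a voxel
phantom, and solved incrementally (geometry updates between load
increments).  Surgery enters through boundary conditions: resection
windows become pressure-loaded free surfaces (blocked where the
temporalis sits behind them); valgization prescribes the fragment's
rigid motion — 2.5 mm shift + 30° hinge rotation by default — to the
tissue in contact, then pressurizes the opened window.  Material
parameters can also be estimated *inversely* from an observed outcome,
in the identifiable coordinates p/E_fat, E_muscle/E_fat and ν.

Package layout: `phantom` (synthetic labelmaps + ground truth,
NIfTI I/O), `meshing` (iso-surfaces, lattice tet meshing, quality),
`surgery` (plans, transforms, boundary conditions), `elasticity` (FEM
core, scenario driver), `outcome` (released volume, proptosis,
comparisons), `inverse` (parameter estimation), `pipeline`/`cli`
(end-to-end runs), `benchmarks` (Lamé sphere, patch-test fixtures).

## Worked example

```sh
python examples/04_compare_scenarios.py
```

prints, on the default synthetic orbit (2 mm mesh, p/E_fat = 0.2):

```
LAVA      area   8.85 cm^2  released  2.62 cm^3  V/A 0.296 cm
two-wall  area  17.24 cm^2  released  0.62 cm^3  V/A 0.036 cm

LAVA releases 8.2x more volume per unit wall area than two-wall resection.
```

Reading: the two-wall resection opens almost twice the wall area, but its
lateral window is blocked by the herniating temporalis, so nearly all of
its 0.62 cm³ outflow squeezes through the floor window.  Valgization
actively relocates the fragment and the temporalis, so the full lateral
space opens: 2.62 cm³ leaves the orbit (almost all of it fat, with a
0.7 mm recession of the eyeball) through half the affected area.  The
per-area ratio is the number to watch — the absolute volumes depend on
the phantom's schematic geometry and the chosen pressure-to-stiffness
ratio (see `docs/methods.md`).

Other examples: `01_generate_phantom.py` (labelmap + analytic volumes),
`02_mesh_and_surfaces.py` (tet model and eyeball surface),
`03_simulate_lava.py` (single scenario), `05_fit_parameters.py`
(inverse recovery).  A thin CLI wraps the pipeline:
`orbitmech simulate --out-dir run/`, plus `phantom`, `mesh`, `plan`,
`compare` and `fit` subcommands.

Label codes (NIfTI labelmaps): 0 background, 1 bone, 2 fat, 3 muscle,
4 bulbus (eyeball), 5 temporalis.

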