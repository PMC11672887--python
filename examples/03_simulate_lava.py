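"""Simulate LAVA (lateral wall valgization) on the default orbit.

Step (i) rigidly shifts the lateral wall fragment 2.5 mm outward and
rotates it 30 degrees about a hinge on its anterior edge; the soft tissue
in contact follows kinematically.  Step (ii) pressurizes the opened
window so fat flows out.  The released volume is the tissue that ends up
outside the original bony cavity.
"""

from orbitmech import (
    MaterialParams, PhantomSpec, build_tet_mesh, compute_outcome,
    generate_phantom, simulate_scenario,
)
from orbitmech.pipeline import default_lava_plan

volume, gt = generate_phantom(PhantomSpec())
mesh = build_tet_mesh(volume, target_edge=2.0, ground_truth=gt)
materials = MaterialParams.orbital_defaults()  # E ratios + p/E set the scale

plan = default_lava_plan(pressure_kpa=0.2)
result = simulate_scenario(mesh, plan, materials, n_steps=10, obstacle=volume)
report = compute_outcome(mesh, result, resolution_mm=0.75)

print(f"valgized fragment area : {report.area_cm2:.2f} cm^2")
print(f"released tissue volume : {report.released_cm3:.2f} cm^3")
print(f"volume per area        : {report.volume_per_area:.3f} cm")
print(f"proptosis change       : {report.proptosis_mm:.2f} mm (positive = "
      "eyeball recedes)")
print("per-tissue breakdown   :",
      {k: round(v, 3) for k, v in report.per_tissue_cm3.items()})
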