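"""Calibrate PLA infill against HU and derive a print plan.

Scans a virtual row of seven 2-cm calibration cubes (infill 45..75 %, the
printer test the physical workflow uses), fits the monotone infill<->HU
curve anchored at air (0 %) and bone (100 %), then inverts it at each
compartment's mean HU to choose infill percentages.
"""

import phantomforge as pf

true_curve = pf.reference_calibration_curve()
cubes, layout = pf.make_cube_phantom(range(45, 80, 5), true_curve, noise_sd=15.0, seed=3)
samples = pf.measure_cubes(cubes, layout["centers_mm"], roi_side_mm=10,
                           infills=layout["infills"])

print("cube measurements (infill % -> mean HU +/- SD):")
for s in samples:
    print(f"  {s.infill:5.1f} %  {s.mean_hu:8.1f} +/- {s.sd_hu:.1f} HU  ({s.roi_voxels} voxels)")

curve = pf.fit_calibration(samples, anchors=(-1000.0, pf.PATIENT_HU["bone"][0]))
targets = {name: mean for name, (mean, _) in pf.PATIENT_HU.items()}
plan = pf.plan_infill(targets, curve, scaffold_floor=10.0, step=2.5)

print("\nprint plan (compartment: target HU -> infill %, predicted HU):")
for name, e in sorted(plan.entries.items(), key=lambda kv: kv[1]["infill"]):
    print(f"  {name:14s} {e['target_hu']:8.2f} HU -> {e['infill']:5.1f} %  "
          f"(predicts {e['predicted_hu']:7.1f} HU)")
print()
print("The air-lungs infill is floored at 10 % - a minimal scaffold is needed")
print("to support the structures above, at the cost of a denser-than-air lung.")
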