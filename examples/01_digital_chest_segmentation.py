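"""Segment a digital chest phantom into the eight tissue compartments.

Builds a synthetic contrast-enhanced chest CT (known ground truth), runs the
HU-range segmentation with the built-in patient scheme, and compares the
result against the generating masks.
"""

import phantomforge as pf

# noiseless chest: each compartment at its published mean HU
spec = pf.DigitalChestSpec(noise_sd=0.0, seed=1, shape=(96, 96, 60), spacing=(4, 4, 4))
volume, truth = pf.make_digital_chest(spec)

scheme = pf.builtin_scheme("patient")
result = pf.segment_compartments(volume, scheme)

print("compartment     DSC vs ground truth")
for name in truth.names:
    dsc = pf.dice(truth.masks[name], result.maskset.masks[name]).dsc
    print(f"  {name:14s} {dsc:.3f}")
print()
print("A DSC of 1.000 means the HU range recovered the compartment exactly;")
print("the NV-lesion scores 0 because its published mean HU (-36.27) lies")
print("outside its own published range (-425..-375), so thresholding cannot")
print("find it - an inconsistency inherited from the source tables.")
print()
rep = result.coverage_report
print(f"scheme overlaps reported: {len(rep.overlaps)} (resolved by priority)")
print(f"voxels outside the body mask (scan-field air): {rep.exterior_voxels}")
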