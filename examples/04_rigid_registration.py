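"""Recover a known phantom misalignment by rigid registration.

Simulates a virtual phantom acquisition displaced by a known rigid pose
(4, -6, 3 mm translation, 3 deg rotation about z) and registers it back to
the source CT with the localized mutual-information metric.
"""

import numpy as np

import phantomforge as pf

spec = pf.DigitalChestSpec(noise_sd=0.0, seed=1, shape=(96, 96, 60), spacing=(4, 4, 4))
volume, truth = pf.make_digital_chest(spec)

curve = pf.reference_calibration_curve()
plan = pf.plan_infill({n: pf.PATIENT_HU[n][0] for n in truth.names}, curve)
transfer = pf.transfer_from_plan(curve, plan)

center = tuple(volume.center_world())
misalignment = pf.RigidTransform((0, 0, np.deg2rad(3.0)), (4.0, -6.0, 3.0), center)
scan = pf.simulate_phantom_scan(
    truth, pf.VirtualScanConfig(transfer, noise_sd=20.0, misalignment=misalignment, seed=9)
)

result = pf.register_rigid(volume, scan, pf.RegistrationConfig(seed=2))
angle_err, shift_err = pf.transform_delta(result.transform, misalignment.inverse())

rot_deg = np.rad2deg(result.transform.rotation)
print(f"applied misalignment : 3.00 deg about z, (4, -6, 3) mm")
print(f"recovered transform  : rotations {rot_deg.round(2)} deg, "
      f"translation {np.round(result.transform.translation, 2)} mm")
print(f"residual error       : {angle_err:.2f} deg, {shift_err:.2f} mm")
print(f"converged            : {result.converged}")
print()
print("Residuals below 1 mm / 1 deg mean mask propagation into the reference")
print("frame costs at most a fraction of a voxel of spatial accuracy.")
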