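"""Generate a synthetic zonal prostate phantom and inspect its anatomy.

The phantom is an ellipsoidal gland partitioned into the four PI-RADS zones
with a 6 mm circular urethra along a curved quadratic centerline, plus a
softened probability volume standing in for a segmentation model's output.
"""

import numpy as np

import zoneline as zl

params = zl.PhantomParams(seed=7)
truth, probs = zl.generate_phantom(params)

print(f"grid {truth.geometry.shape} at {truth.geometry.spacing_mm} mm (row, col, slice)")
print(zl.structure_volumes(truth).to_string(index=False))
# volume_cm3 is voxel count x voxel volume; proportions are relative to the
# whole gland, so the five structures sum to 1.

mismatch = int((zl.argmax_labels(probs).data != truth.data).sum())
print(f"\nvoxels where the softened probabilities disagree with truth: {mismatch}")
print("(Gaussian blur of {:.1f} mm and {:.0%} top-two swap noise)".format(
    params.blur_sigma_mm, params.noise_rate))

curve = params.true_curve()
z_mid = truth.geometry.slice_z(truth.geometry.shape[0] // 2)
print(f"true centerline at mid-gland (z={z_mid:.1f} mm): x,y = {np.round(curve(z_mid), 2)} mm")
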