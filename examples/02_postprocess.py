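"""Reconstruct an anatomically consistent label map from probability maps.

Runs the six-step post-processing chain — largest-component gland extraction,
per-slice urethra candidates, weighted quadratic centerline fit, 6 mm circle
rasterisation, per-zone largest components, nearest-zone fill — and compares
the result with the known phantom truth.
"""

import numpy as np

import zoneline as zl

truth, probs = zl.generate_phantom(zl.PhantomParams(seed=7))
res = zl.postprocess_case(probs, full_output=True)
geom = truth.geometry

print(f"slice candidates used for the centerline fit: {len(res.candidates)}")
print(f"fitted x(z) coefficients: {np.round(res.curve.coeff_x, 5)}")
print(f"fitted y(z) coefficients: {np.round(res.curve.coeff_y, 5)}")

# the output foreground is exactly the extracted gland; urethra + four zones
# partition it with no interior background
assert np.array_equal(res.labels.foreground(), res.prostate_mask)

print(f"\nprostate DSC vs truth: {zl.dsc(res.labels.foreground(), truth.foreground()):.4f}")
c = zl.cld(zl.centerline(res.labels.mask(1), geom), zl.centerline(truth.mask(1), geom))
print(f"urethra centerline distance vs truth: {c:.2f} mm")
print("(CLD is the mean symmetric nearest-neighbour distance between the two"
      " per-slice centerlines; sub-voxel values mean near-perfect recovery)")
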