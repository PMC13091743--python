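# zoneline

Anatomically consistent post-processing and evaluation of zonal prostate
segmentations.

## The problem

Semantic-segmentation models for prostate MRI emit per-voxel class
probabilities for the background, the prostatic urethra and the four
PI-RADS zones — peripheral (PZ), central (CZ), transitional (TZ) and the
anterior fibromuscular stroma (AFS). Voxel-wise hard assignment of those
probabilities produces output that violates the conventions radiotherapy
delineation protocols rely on: ragged or fragmented urethras (protocols
draw the urethra as a fixed **6 mm diameter circle on each axial slice**),
satellite blobs outside the gland, and background holes inside it.

`zoneline` reconstructs a protocol-conformant label map from any model's
probability maps, and provides the evaluation-metric suite used to compare
segmentations against expert readers, a synthetic phantom generator for
testing without clinical data, and a paired cohort-comparison harness.

## The reconstruction

Given a probability volume `P(c | v)` over classes
{background, urethra, PZ, CZ, TZ, AFS}:

1. **Gland**: the prostate mask is the largest 26-connected component of
   `{v : argmax_c P(c|v) ≠ background}`, with enclosed cavities filled.
2. **Centerline candidates**: per axial slice, the voxel maximising the
   urethra probability (centre of mass on ties) gives a point
   `(x_i, y_i, z_i)` with weight `w_i = max P(urethra)`.
3. **Centerline fit**: two independent weighted least-squares quadratics in
   physical mm, `x(z) = a_x z² + b_x z + c_x` and likewise `y(z)`,
   minimising `Σ w_i r_i²` (degree reduced when fewer than 3 slices).
4. **Urethra**: a 6 mm diameter disc rasterised around `(x(z), y(z))` on
   every gland-bearing slice, clipped to the gland.
5. **Zones**: each zone keeps its largest 26-connected component.
6. **Fill**: every remaining gland voxel joins the zone with the nearest
   retained voxel in mm (ties to the lowest label code).

The output partitions the gland exactly: urethra ∪ PZ ∪ CZ ∪ TZ ∪ AFS =
gland, pairwise disjoint, no interior background.

## The metrics

* **DSC** = `2|A∩B| / (|A|+|B|)` — volume overlap.
* **SDSC(τ)** — fraction of pooled boundary points of both structures
  within τ mm of the other boundary (τ = 1 mm by default).
* **pSSD(p)** — the p-th percentile of all pooled boundary
  nearest-neighbour distances; `pSSD(100)` is the symmetric Hausdorff
  distance.
* **CLD** — mean symmetric 3D nearest-neighbour distance between the two
  per-slice urethra centerlines, **including** slices present in only one
  segmentation (such a slice contributes at least the slice thickness).

All distances are computed in mm on anisotropic grids (voxel-centre
convention).

## Worked example

```python
import zoneline as zl

truth, probs = zl.generate_phantom(zl.PhantomParams(seed=7))
pred = zl.postprocess_case(probs)
report = zl.evaluate_case(pred, truth, tau_mm=1.0)
```

Running `python examples/03_metrics.py` (which does exactly this) prints:

```
structure     DSC  SDSC(1mm)    P50    P80    P95
 prostate   0.995      0.986   0.00   0.00   0.50
       PZ   0.986      0.986   0.00   0.00   0.50
       CZ   0.952      0.982   0.00   0.00   0.50
       TZ   0.971      0.962   0.00   0.00   1.00
      AFS   0.976      0.991   0.00   0.00   0.50
  urethra   0.714      0.793   0.71   1.12   1.50

urethra CLD: 1.44 mm
```

i.e. the reconstruction recovers the phantom gland and zones almost
perfectly from blurred, noise-corrupted probabilities (DSC ≥ 0.95
everywhere, boundary errors at or below one voxel for 80 % of boundary
points), while the urethra — the hardest, thinnest structure — is placed
within ~1.4 mm of the true centerline. See `examples/` for phantom
generation, post-processing internals and the paired cohort comparison.

## Command line

```bash
zoneline phantom --seed 3 --out-dir case/ --readers 2
zoneline postprocess --probs case/probabilities.nii.gz --out pred.nii.gz
zoneline evaluate --pred pred.nii.gz --ref case/truth.nii.gz --out report.csv
zoneline evaluate-cohort --manifest cohort.csv --out results/
```

Volumes are NIfTI-1 (`.nii`/`.nii.gz`); probability maps are one 4D file
(class as 4th axis) or per-class 3D files `{stem}_class{code}.nii.gz`.

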