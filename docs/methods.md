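# Methods

This note documents the models, conventions and numerical choices behind
`zoneline`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic tests do and do not
demonstrate about clinical data.

## Coordinate and data model

Arrays are ordered `(slice, row, column)`; the slice axis is the axial
(superior–inferior) direction along which delineation protocols operate.
Voxel `(i, j, k)` maps to the **centre** point
`(origin_x + k·Δcol, origin_y + j·Δrow, origin_z + i·Δslice)` in mm, so all
distances are physical and spacing-aware; typical grids are 0.4–0.5 mm
in-plane with 2.5–3.6 mm slices. NIfTI-1 files are written with the disk
axes `(column, row, slice)` so the affine's x/y/z match these physical
axes. Rotated or sheared affines are not interpreted — the package reads
spacings and origins only, and resampling between geometries is out of
scope.

Probability volumes must sum to 1 per voxel. Exported maps are lossy
(float16 rounding, compression), so sums within 1e-3 of 1 are silently
renormalised; larger deviations are rejected as a sign of mismatched or
corrupted inputs.

## Post-processing chain

**Gland extraction.** "Inverse of the background" is read as
`argmax ≠ background` — threshold-free and the conventional decoding of
semantic-segmentation output. Connected components use 26-connectivity,
the permissive standard for anatomical blobs. Enclosed background cavities
of the winning component are filled (`binary_fill_holes`): a cavity inside
the gland is anatomically part of the gland, and filling it at the mask
stage is what lets the nearest-zone assignment absorb interior
misclassifications while keeping the partition invariant (output
foreground ≡ extracted gland) exact. Cavities open to the volume boundary
are not enclosed and remain background.

**Centerline candidates.** One candidate per gland-bearing slice with
positive urethra probability: the argmax voxel centre, or the centre of
mass of all tied argmax voxels. The candidate weight is the maximal
probability itself.

**Centerline fit.** The "3D 2nd-degree polynomial" is realised as a
parametric pair of independent 1D weighted least-squares fits, `x(z)` and
`y(z)`, in mm — the natural form for a structure defined per axial slice,
and spacing-invariant because the fit happens in physical coordinates.
The objective is `Σ wᵢ rᵢ²` (implemented by passing `√w` to
`numpy.polyfit`), so zero-weight candidates drop out exactly. With fewer
than three distinct candidate slices the degree reduces to
`n_distinct − 1`; only a complete absence of candidates raises an error,
so degenerate cases cannot crash a batch run. If every weight is zero the
fit falls back to uniform weights with a warning.

**Urethra rasterisation.** On every slice containing gland voxels the
curve is evaluated (extrapolating beyond the candidate range) and all
voxels whose in-plane centre lies within `diameter/2` (default 3 mm) of
the curve point are included, then clipped to the gland. The voxel
containing the curve point is always included first, so the urethra never
vanishes on coarse grids. Drawing on every gland slice and clipping
realises "a circle on each slice where the gland is present".

**Zone resolution.** Initial zone labels are the per-voxel argmax
restricted to voxels whose winner is a zone; each zone keeps only its
largest 26-connected component; remaining gland voxels (argmax background,
argmax urethra outside the drawn circle, discarded satellites) adopt the
zone of the nearest retained voxel in physical mm. Equidistant ties break
to the lowest label code — deterministic and testable. Below 64³ voxels
the assignment is an exact brute-force scan; above, per-zone exact
Euclidean distance transforms (`distance_transform_edt` with anisotropic
sampling); tests assert the two routes agree. The chain is fully
deterministic: identical inputs give bit-identical outputs.

## Metrics

Surfaces are **border-voxel centres**: mask voxels with a 6-neighbour
outside the mask (grid borders count as outside). This representation is
simple, spacing-aware and makes sub-voxel surface-distance values (e.g.
0.50 mm at 0.5 mm spacing) representable. Pooled symmetric distances are
nearest-neighbour point distances in mm computed with a k-d tree, which
tests verify against O(n²) brute force.

Percentiles (pSSD) use linear interpolation between order statistics, the
most common convention. Note a subtlety: the duality
`SDSC(τ) ≥ p/100 ⟺ pSSD(p) ≤ τ` holds exactly only for the pure
order-statistic (inverse-CDF) percentile; `pssd(..., method="inverted_cdf")`
exposes that variant and the property suite asserts the duality with it.

The urethra centerline is the per-slice in-plane centroid of the mask —
the skeleton of a per-slice disc, matching how the structure is defined —
rather than a generic 3D thinning. CLD is the mean symmetric 3D
nearest-neighbour distance over **all** points of both centerlines;
a slice present in only one segmentation therefore contributes at least
the slice thickness, penalising unilateral extent instead of ignoring it.

Empty-structure conventions (not exercised by protocol data but needed for
robustness): DSC/SDSC are 1 when both masks are empty and 0 when exactly
one is; distance metrics require non-empty inputs and are reported as NaN
in batch evaluation.

## Phantom generator

The generator emulates the *structure* of zonal delineation datasets, not
their image content: an ellipsoidal gland (default semi-axes 20×17×30 mm,
≈ 43 cm³, a typical gland volume) partitioned into an anterior AFS cap
(5 mm), a basal CZ wedge (9 mm), a central TZ ellipsoid (gland minus the
6 mm peripheral shell) and the PZ remainder, with the 6 mm urethra drawn
along a gently curved quadratic centerline (≈ 2–5 mm bow across the
gland). Defaults: 96×96×24 voxels at 0.5×0.5×3.0 mm, configurable to
0.41×0.41×2.5 mm.

The soft "model output" is the one-hot truth blurred with a Gaussian of
σ = 0.8 mm and renormalised, then corrupted by swapping the top-two class
probabilities at a fraction (default 2 %) of voxels. Blur creates the
ambiguous boundaries and swap noise the local misclassifications that the
post-processing targets. All randomness flows from one integer seed
through one `numpy` generator per phantom, so fixtures are
bit-reproducible.

`perturb_reader` simulates an independent re-delineation: a smooth random
displacement field (normalised so the **maximum** displacement equals the
stated amplitude) warps all labels with nearest-neighbour sampling, and
the urethra is re-drawn as fixed-diameter circles around the per-slice
centerline jittered by a smooth offset of bounded magnitude; vacated
voxels re-join the nearest zone so the partition invariant is preserved.
Zero amplitudes return the input unchanged.

What the phantom does **not** model: MR intensities, inter-patient
anatomical variation, true zonal boundary morphology (the partition is
stylised but topologically plausible), reader-specific systematic bias,
and model failure modes beyond boundary blur and local flips. Passing
tests therefore demonstrate the correctness and internal consistency of
the reconstruction and metrics under controlled conditions, not clinical
segmentation accuracy.

## Cohort analysis

Per-case metric reports are summarised as median and inter-quartile range
(quartiles by linear interpolation). Each model-vs-reader metric is
compared against the inter-reader baseline on the same cases with the
paired two-sided Wilcoxon signed-rank test (`scipy.stats.wilcoxon`,
`wilcox` zero-handling, p = 1 by convention when all differences are
zero), with a Shapiro–Wilk normality screen on the differences recorded
alongside; no multiple-testing correction. These are textbook tests
delegated to scipy — the package's contribution is the harness, pairing
and conventions, all pinned for reproducibility. Welch-type volume
comparisons are not re-implemented; `structure_volumes` provides the
per-structure volumes (cm³) and zonal proportions they would consume.

## Problem sizes and tolerances

The test and acceptance workloads use the default 96×96×24 phantom for
end-to-end runs (10 seeds per noise level), a 192×192×16 grid at 0.25 mm
for the urethra-geometry check, 50 random ≤ 16³ mask pairs for the
brute-force oracle comparison, and 20-case cohorts on a 64×64×16 phantom
for the paired statistics — sizes chosen so the whole suite runs on a
laptop in a couple of minutes while still exercising anisotropy,
clipping and degenerate branches. Exact-recovery assertions use 1e-9
coefficient tolerance; oracle comparisons 1e-9 mm; end-to-end recovery
asserts gland DSC ≥ 0.95 and urethra CLD within one in-plane voxel
diagonal plus the centerline fit residual.

## Known limitations

* The centerline is global and quadratic; a strongly S-shaped urethra
  would be under-fitted by design (the protocol the output mimics makes
  the same trade).
* Candidate extraction trusts the per-slice probability argmax; a model
  that hallucinates high urethra probability far from the gland on many
  slices can bend the fit (weights mitigate, clipping bounds the damage).
* CLD nearest-neighbour search is 3D, not slice-constrained; other
  implementations may differ in the exact value while sharing the
  slice-inclusion property.
* No DICOM/RT-STRUCT I/O and no resampling: inputs must share one grid.
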