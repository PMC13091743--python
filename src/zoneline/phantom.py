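"""Synthetic prostate phantoms with known ground truth.

The generator emulates the structure of manually delineated zonal prostate
datasets: an ellipsoidal gland partitioned into the four PI-RADS zones
(posterior peripheral shell PZ, central transition ellipsoid TZ, basal
central-zone wedge CZ, anterior fibromuscular cap AFS) traversed by a
urethra drawn as a 6 mm diameter disc on each axial slice along a gently
curved quadratic centerline.  Grids default to 96×96 in-plane voxels at
0.5 mm with 24 slices of 3.0 mm, and can be reconfigured to e.g.
0.41×0.41×2.5 mm to mimic other scanners.

From the truth label map a soft "model output" is derived by Gaussian
blurring of the one-hot encoding (ambiguous boundaries) plus optional
top-two probability swap noise (local misclassification) — the failure
modes that anatomical post-processing is designed to repair.  A reader
perturbation operator produces plausible second-opinion delineations by
smooth boundary warping and centerline jitter, enabling inter-reader-style
paired evaluations.  All randomness flows from a single integer seed, so
every phantom is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyZoneWarning, ZoneFallbackWarning
from .postprocess import QuadraticCurve, UrethraGeometrySpec, rasterise_urethra
from .volumes import (
    DEFAULT_SCHEMA,
    LabelSchema,
    LabelVolume,
    ProbabilityVolume,
    VolumeGeometry,
    one_hot,
)

__all__ = ["PhantomParams", "ReaderPerturbation", "generate_phantom", "perturb_reader"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and noise parameters of a synthetic phantom.

    Distances are mm.  The zone partition is stylised but topologically
    plausible; the urethra curve coefficients are expressed relative to the
    gland centre (``x(dz) = a dz² + b dz + c`` with ``dz = z - z_centre``).
    """

    shape: tuple[int, int, int] = (24, 96, 96)  # (slices, rows, cols)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 3.0)  # (row, col, slice)
    prostate_semiaxes_mm: tuple[float, float, float] = (20.0, 17.0, 30.0)  # (x, y, z)
    pz_shell_mm: float = 6.0  # peripheral shell thickness
    tz_semiaxes_mm: tuple[float, float, float] | None = None  # default: prostate − shell
    cz_base_mm: float = 9.0  # basal wedge extent along z
    afs_cap_mm: float = 5.0  # anterior cap thickness
    urethra_rel_coeff_x: tuple[float, float, float] = (0.004, 0.0, 0.0)
    urethra_rel_coeff_y: tuple[float, float, float] = (-0.006, 0.0, 0.0)
    urethra_diameter_mm: float = 6.0
    blur_sigma_mm: float = 0.8
    noise_rate: float = 0.02
    seed: int = 0
    schema: LabelSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        for name in ("pz_shell_mm", "cz_base_mm", "afs_cap_mm", "urethra_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be non-negative")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(spacing_mm=self.spacing_mm, origin_mm=(0.0, 0.0, 0.0), shape=self.shape)

    @property
    def centre_mm(self) -> tuple[float, float, float]:
        g = self.geometry
        n_slices, n_rows, n_cols = g.shape
        return (
            (n_cols - 1) / 2.0 * g.col_spacing,
            (n_rows - 1) / 2.0 * g.row_spacing,
            (n_slices - 1) / 2.0 * g.slice_spacing,
        )

    def true_curve(self) -> QuadraticCurve:
        """Absolute-coordinate quadratic centerline of the phantom urethra."""
        cx, cy, cz = self.centre_mm

        def shift(rel: tuple[float, float, float], c0: float) -> tuple[float, float, float]:
            a, b, c = rel
            # expand a(z-cz)^2 + b(z-cz) + c + c0 in powers of z
            return (a, b - 2 * a * cz, a * cz**2 - b * cz + c + c0)

        return QuadraticCurve(
            shift(self.urethra_rel_coeff_x, cx), shift(self.urethra_rel_coeff_y, cy)
        )


@dataclass(frozen=True)
class ReaderPerturbation:
    """Simulated independent re-delineation of a phantom truth."""

    boundary_jitter_mm: float = 1.5
    urethra_jitter_mm: float = 1.5
    urethra_diameter_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_mm < 0 or self.urethra_jitter_mm < 0:
            raise ValueError("jitter amplitudes must be non-negative")
        if self.urethra_diameter_mm <= 0:
            raise ValueError("urethra diameter must be strictly positive")


def _mm_grids(geom: VolumeGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, y, z) mm coordinate arrays broadcastable to the (slice, row, col) grid."""
    n_slices, n_rows, n_cols = geom.shape
    z = (geom.origin_mm[2] + np.arange(n_slices) * geom.slice_spacing)[:, None, None]
    y = (geom.origin_mm[1] + np.arange(n_rows) * geom.row_spacing)[None, :, None]
    x = (geom.origin_mm[0] + np.arange(n_cols) * geom.col_spacing)[None, None, :]
    return x, y, z


def _truth_labels(params: PhantomParams) -> LabelVolume:
    geom = params.geometry
    schema = params.schema
    cx, cy, cz = params.centre_mm
    ax, ay, az = params.prostate_semiaxes_mm
    x, y, z = _mm_grids(geom)

    prostate = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    if not prostate.any():
        raise ValueError("prostate ellipsoid contains no voxels on this grid")

    tz_axes = params.tz_semiaxes_mm
    if tz_axes is None:
        tz_axes = tuple(max(s - params.pz_shell_mm, 1.0) for s in params.prostate_semiaxes_mm)
    tzx, tzy, tzz = tz_axes
    inner = ((x - cx) / tzx) ** 2 + ((y - cy) / tzy) ** 2 + ((z - cz) / tzz) ** 2 <= 1.0

    # anterior = -y direction; base (superior) = +z
    afs = prostate & (y - cy <= -(ay - params.afs_cap_mm))
    czone = prostate & ~afs & (z - cz >= az - params.cz_base_mm)
    tz = prostate & ~afs & ~czone & inner
    pz = prostate & ~afs & ~czone & ~inner

    labels = np.zeros(geom.shape, dtype=np.int16)
    labels[pz] = schema.code_of("PZ")
    labels[czone] = schema.code_of("CZ")
    labels[tz] = schema.code_of("TZ")
    labels[afs] = schema.code_of("AFS")

    urethra = rasterise_urethra(
        params.true_curve(), prostate, geom, UrethraGeometrySpec(params.urethra_diameter_mm)
    )
    if not urethra.any():
        raise ValueError("urethra curve exits the prostate on every slice")
    labels[urethra] = schema.urethra_code

    for name in ("PZ", "CZ", "TZ", "AFS"):
        if not np.any(labels == schema.code_of(name)):
            warnings.warn(f"phantom zone {name} is empty under these parameters", EmptyZoneWarning)
    return LabelVolume(geom, labels, schema)


def _soften(truth: LabelVolume, params: PhantomParams) -> ProbabilityVolume:
    probs = one_hot(truth)
    geom = truth.geometry
    if params.blur_sigma_mm > 0:
        sigma_vox = tuple(params.blur_sigma_mm / s for s in geom.sampling)
        data = np.stack([ndimage.gaussian_filter(f, sigma=sigma_vox) for f in probs.data])
        data /= data.sum(axis=0)
    else:
        data = probs.data.copy()

    if params.noise_rate > 0:
        rng = np.random.default_rng(params.seed)
        flip = rng.random(geom.shape) < params.noise_rate
        idx = np.argwhere(flip)
        if len(idx):
            cols = data[:, idx[:, 0], idx[:, 1], idx[:, 2]]  # (n_classes, n_flips)
            order = np.argsort(cols, axis=0)
            top, second = order[-1], order[-2]
            n = np.arange(cols.shape[1])
            cols[top, n], cols[second, n] = cols[second, n].copy(), cols[top, n].copy()
            data[:, idx[:, 0], idx[:, 1], idx[:, 2]] = cols
    return ProbabilityVolume(geom, data, truth.schema)


def generate_phantom(params: PhantomParams = PhantomParams()) -> tuple[LabelVolume, ProbabilityVolume]:
    """Build a ground-truth label volume and its softened probability volume.

    With ``blur_sigma_mm = 0`` and ``noise_rate = 0`` the probability volume
    is the exact one-hot encoding of the truth.  Identical parameters
    (including the seed) produce bit-identical outputs.
    """
    truth = _truth_labels(params)
    return truth, _soften(truth, params)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Smooth random scalar field scaled to max |value| = 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _warp_labels(labels: np.ndarray, geom: VolumeGeometry, amplitude_mm: float, rng) -> np.ndarray:
    """Displace labels by a smooth random field with max displacement = amplitude."""
    sigma = (1.5, 8.0, 8.0)  # voxels: gentle in-plane, mild across slices
    disp_vox = np.stack([_smooth_unit_field(rng, labels.shape, sigma) for _ in range(3)])
    spacing = np.asarray(geom.sampling)[:, None, None, None]
    peak_mm = np.sqrt(((disp_vox * spacing) ** 2).sum(axis=0)).max()
    if peak_mm > 0:
        disp_vox *= amplitude_mm / peak_mm
    coords = np.indices(labels.shape, dtype=float) + disp_vox
    return ndimage.map_coordinates(labels, coords, order=0, mode="nearest")


def _jitter_offsets(rng, n: int, amplitude_mm: float) -> np.ndarray:
    """Smooth per-slice (dx, dy) offsets with max in-plane norm = amplitude."""
    if amplitude_mm == 0 or n == 0:
        return np.zeros((n, 2))
    raw = ndimage.gaussian_filter1d(rng.standard_normal((2, n)), sigma=2.0, axis=1)
    norms = np.sqrt((raw**2).sum(axis=0))
    peak = norms.max()
    if peak == 0:
        return np.zeros((n, 2))
    return (raw / peak * amplitude_mm).T


def perturb_reader(truth: LabelVolume, p: ReaderPerturbation) -> LabelVolume:
    """Simulate an independent reader's delineation of a phantom case.

    Boundaries are displaced by a smooth random field of at most
    ``boundary_jitter_mm``; the urethra is then re-drawn as fixed-diameter
    circles around the (possibly warped) per-slice centerline jittered by at
    most ``urethra_jitter_mm``, and vacated voxels are re-assigned to the
    nearest zone so the partition invariant is preserved.  Zero amplitudes
    reproduce the input exactly.
    """
    geom = truth.geometry
    schema = truth.schema
    if p.boundary_jitter_mm == 0 and p.urethra_jitter_mm == 0:
        return LabelVolume(geom, truth.data.copy(), schema)

    rng = np.random.default_rng(p.seed)
    labels = truth.data.copy()
    if p.boundary_jitter_mm > 0:
        labels = _warp_labels(labels, geom, p.boundary_jitter_mm, rng)

    ucode = schema.urethra_code
    urethra_old = labels == ucode
    prostate = labels != 0
    if not urethra_old.any() or not prostate.any():
        return LabelVolume(geom, labels, schema)

    # jittered per-slice centres of the current urethra
    slices = np.flatnonzero(urethra_old.any(axis=(1, 2)))
    centres = np.empty((len(slices), 2))
    for n, i in enumerate(slices):
        rows, cols = np.nonzero(urethra_old[i])
        centres[n, 0] = geom.origin_mm[0] + cols.mean() * geom.col_spacing
        centres[n, 1] = geom.origin_mm[1] + rows.mean() * geom.row_spacing
    centres += _jitter_offsets(rng, len(slices), p.urethra_jitter_mm)

    radius = p.urethra_diameter_mm / 2.0
    xg, yg = geom.inplane_coords()
    urethra_new = np.zeros_like(urethra_old)
    for (cx, cy), i in zip(centres, slices):
        disc = (xg - cx) ** 2 + (yg - cy) ** 2 <= radius**2
        j = int(round((cy - geom.origin_mm[1]) / geom.row_spacing))
        k = int(round((cx - geom.origin_mm[0]) / geom.col_spacing))
        if 0 <= j < disc.shape[0] and 0 <= k < disc.shape[1]:
            disc[j, k] = True
        urethra_new[i] = disc & prostate[i]

    labels[urethra_old] = 0
    labels[urethra_new] = ucode

    vacated = prostate & (labels == 0)
    if vacated.any():
        zone_masks = {c: labels == c for c in schema.zone_codes if np.any(labels == c)}
        if zone_masks:
            codes = sorted(zone_masks)
            dists = np.stack(
                [
                    ndimage.distance_transform_edt(~zone_masks[c], sampling=geom.sampling)
                    for c in codes
                ]
            )
            winner = np.asarray(codes, dtype=np.int16)[np.argmin(dists, axis=0)]
            labels[vacated] = winner[vacated]
        else:
            warnings.warn("no zones available to absorb vacated voxels", ZoneFallbackWarning)
    return LabelVolume(geom, labels, schema)
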