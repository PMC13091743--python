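"""Data model and NIfTI I/O for label and class-probability volumes.

The package works on axial MR-style grids with anisotropic voxel spacing.
Arrays are kept in ``(slice, row, column)`` order — the slice axis is the
anatomical superior-inferior axis along which the urethra centerline is
parameterised.  All physical distances are in millimetres and refer to
voxel *centres*: voxel ``(i, j, k)`` sits at

    x = origin_x + k * spacing_column
    y = origin_y + j * spacing_row
    z = origin_z + i * spacing_slice

so ``x`` runs along columns, ``y`` along rows and ``z`` across slices.

Volumes are read and written as NIfTI-1 files through :mod:`nibabel`.
Probability volumes accept either a single 4D file (class as 4th axis) or a
set of per-class 3D files named ``{stem}_class{code}.nii.gz``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    GeometryMismatchError,
    ProbabilityNormalisationError,
    SchemaValidationError,
)

__all__ = [
    "LabelSchema",
    "DEFAULT_SCHEMA",
    "VolumeGeometry",
    "ProbabilityVolume",
    "LabelVolume",
    "read_label_volume",
    "write_label_volume",
    "read_probability_volume",
    "write_probability_volume",
    "one_hot",
    "argmax_labels",
]

#: Tolerated per-voxel drift of the class-probability sum from 1.  Sums within
#: this tolerance are silently renormalised (exported probability maps are
#: lossy); larger deviations raise.
PROB_SUM_TOLERANCE = 1e-3

#: Tolerance used when *validating* an already-normalised volume.
PROB_SUM_STRICT = 1e-5


@dataclass(frozen=True)
class LabelSchema:
    """Mapping of integer label codes to structure names.

    Code 0 is always the background class.  The default schema covers the
    six classes of zonal prostate segmentation: background, urethra and the
    four PI-RADS zones (PZ, CZ, TZ, AFS).
    """

    codes: Mapping[int, str] = field(
        default_factory=lambda: {
            0: "background",
            1: "urethra",
            2: "PZ",
            3: "CZ",
            4: "TZ",
            5: "AFS",
        }
    )

    def __post_init__(self) -> None:
        codes = dict(self.codes)
        if any(c < 0 for c in codes):
            raise SchemaValidationError("label codes must be non-negative")
        if codes.get(0) != "background":
            raise SchemaValidationError("code 0 must map to 'background'")
        if len(set(codes.values())) != len(codes):
            raise SchemaValidationError("structure names must be unique")
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def sorted_codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.codes))

    @property
    def zone_codes(self) -> tuple[int, ...]:
        """Codes of the anatomical zones (everything except background and urethra)."""
        return tuple(c for c in self.sorted_codes if c not in (0, self.urethra_code))

    @property
    def urethra_code(self) -> int:
        for code, name in self.codes.items():
            if name == "urethra":
                return code
        raise SchemaValidationError("schema has no 'urethra' structure")

    def name_of(self, code: int) -> str:
        return self.codes[code]

    def code_of(self, name: str) -> int:
        for code, n in self.codes.items():
            if n == name:
                return code
        raise KeyError(name)


DEFAULT_SCHEMA = LabelSchema()


@dataclass(frozen=True)
class VolumeGeometry:
    """Binds the voxel grid to physical space.

    Parameters
    ----------
    spacing_mm:
        ``(row, column, slice)`` voxel pitch in mm; all strictly positive.
        In-plane spacings of clinical T2w series are typically 0.4-0.5 mm
        with slice thickness 2.5-3.6 mm.
    origin_mm:
        ``(x, y, z)`` position of voxel ``(0, 0, 0)``'s centre in mm.
    shape:
        ``(slices, rows, columns)`` grid size.
    """

    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def row_spacing(self) -> float:
        return self.spacing_mm[0]

    @property
    def col_spacing(self) -> float:
        return self.spacing_mm[1]

    @property
    def slice_spacing(self) -> float:
        return self.spacing_mm[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def inplane_diagonal_mm(self) -> float:
        """Length of the in-plane voxel diagonal, a natural discretisation scale."""
        return float(np.hypot(self.row_spacing, self.col_spacing))

    # array-order (slice, row, col) sampling steps, used by distance transforms
    @property
    def sampling(self) -> tuple[float, float, float]:
        return (self.slice_spacing, self.row_spacing, self.col_spacing)

    def slice_z(self, i) -> np.ndarray | float:
        """z coordinate (mm) of slice centre(s) ``i``."""
        return self.origin_mm[2] + np.asarray(i, dtype=float) * self.slice_spacing

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices ``(i=slice, j=row, k=col)`` to ``(x, y, z)`` mm.

        Accepts an ``(N, 3)`` array or a single triple; returns the same shape.
        """
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = np.empty_like(ijk)
        out[:, 0] = self.origin_mm[0] + ijk[:, 2] * self.col_spacing
        out[:, 1] = self.origin_mm[1] + ijk[:, 1] * self.row_spacing
        out[:, 2] = self.origin_mm[2] + ijk[:, 0] * self.slice_spacing
        return out if out.shape[0] > 1 else out[0]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_mm` (continuous indices, not rounded)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        out = np.empty_like(xyz)
        out[:, 0] = (xyz[:, 2] - self.origin_mm[2]) / self.slice_spacing
        out[:, 1] = (xyz[:, 1] - self.origin_mm[1]) / self.row_spacing
        out[:, 2] = (xyz[:, 0] - self.origin_mm[0]) / self.col_spacing
        return out if out.shape[0] > 1 else out[0]

    def inplane_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` mm coordinate grids of shape ``(rows, cols)``."""
        _, n_rows, n_cols = self.shape
        x = self.origin_mm[0] + np.arange(n_cols, dtype=float) * self.col_spacing
        y = self.origin_mm[1] + np.arange(n_rows, dtype=float) * self.row_spacing
        return np.meshgrid(x, y, indexing="xy")

    def same_grid(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )


def _require_same_grid(a: VolumeGeometry, b: VolumeGeometry) -> None:
    if not a.same_grid(b):
        raise GeometryMismatchError(
            f"volumes are on different grids: {a.shape}@{a.spacing_mm} vs {b.shape}@{b.spacing_mm}"
        )


@dataclass
class LabelVolume:
    """Integer-coded segmentation over a physical grid."""

    geometry: VolumeGeometry
    data: np.ndarray
    schema: LabelSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int16)
            else:
                raise SchemaValidationError("label data must be integer-valued")
        if self.data.shape != self.geometry.shape:
            raise GeometryMismatchError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )
        present = np.unique(self.data)
        bad = sorted(set(present.tolist()) - set(self.schema.sorted_codes))
        if bad:
            raise SchemaValidationError(f"labels contain codes outside the schema: {bad}")

    def mask(self, code: int) -> np.ndarray:
        return self.data == code

    def foreground(self) -> np.ndarray:
        """Union of all non-background structures (the 'prostate' in this schema)."""
        return self.data != 0


@dataclass
class ProbabilityVolume:
    """Per-class soft segmentation output.

    ``data`` has shape ``(n_classes, slices, rows, cols)`` with class index
    following ``schema.sorted_codes`` order; per-voxel sums are 1.
    """

    geometry: VolumeGeometry
    data: np.ndarray
    schema: LabelSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (len(self.schema),) + self.geometry.shape
        if self.data.shape != expected:
            raise GeometryMismatchError(
                f"probability data shape {self.data.shape} != expected {expected}"
            )
        if self.data.min() < -PROB_SUM_TOLERANCE or self.data.max() > 1 + PROB_SUM_TOLERANCE:
            raise ProbabilityNormalisationError("class probabilities must lie in [0, 1]")
        sums = self.data.sum(axis=0)
        dev = np.abs(sums - 1.0)
        if dev.max() > PROB_SUM_TOLERANCE:
            raise ProbabilityNormalisationError(
                f"per-voxel probability sums deviate from 1 by up to {dev.max():.3g} "
                f"(tolerance {PROB_SUM_TOLERANCE:g})"
            )
        if dev.max() > PROB_SUM_STRICT:
            self.data = np.clip(self.data, 0.0, None) / self.data.sum(axis=0)

    def class_field(self, code: int) -> np.ndarray:
        """3D probability field of the class with the given schema code."""
        idx = self.schema.sorted_codes.index(code)
        return self.data[idx]


def one_hot(labels: LabelVolume) -> ProbabilityVolume:
    """Encode a label volume as a degenerate (0/1) probability volume."""
    codes = labels.schema.sorted_codes
    data = np.stack([(labels.data == c).astype(np.float64) for c in codes])
    return ProbabilityVolume(labels.geometry, data, labels.schema)


def argmax_labels(prob: ProbabilityVolume) -> LabelVolume:
    """Hard-assign each voxel to its most probable class."""
    codes = np.asarray(prob.schema.sorted_codes)
    return LabelVolume(prob.geometry, codes[np.argmax(prob.data, axis=0)], prob.schema)


# ---------------------------------------------------------------------------
# NIfTI I/O.  On disk the voxel axes are (column, row, slice) so that the
# NIfTI affine's x/y/z match the package's physical axes; internally arrays
# are transposed to (slice, row, column).
# ---------------------------------------------------------------------------


def _affine(geom: VolumeGeometry) -> np.ndarray:
    aff = np.diag([geom.col_spacing, geom.row_spacing, geom.slice_spacing, 1.0])
    aff[:3, 3] = geom.origin_mm
    return aff


def _geometry_from_img(img: nib.Nifti1Image) -> VolumeGeometry:
    zooms = img.header.get_zooms()[:3]  # (col, row, slice) on disk
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    n_cols, n_rows, n_slices = img.shape[:3]
    return VolumeGeometry(
        spacing_mm=(float(zooms[1]), float(zooms[0]), float(zooms[2])),
        origin_mm=origin,
        shape=(n_slices, n_rows, n_cols),
    )


def read_label_volume(path: str | os.PathLike, schema: LabelSchema = DEFAULT_SCHEMA) -> LabelVolume:
    """Read an integer label volume from a NIfTI-1 file.

    Raises
    ------
    FileNotFoundError, SchemaValidationError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    disk = np.asanyarray(img.dataobj)
    if not np.all(disk == np.round(disk)):
        raise SchemaValidationError(f"{path} contains non-integer label data")
    data = np.ascontiguousarray(disk.astype(np.int16).transpose(2, 1, 0))
    return LabelVolume(_geometry_from_img(img), data, schema)


def write_label_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as an integer-typed NIfTI-1 file."""
    disk = np.ascontiguousarray(volume.data.astype(np.int16).transpose(2, 1, 0))
    img = nib.Nifti1Image(disk, _affine(volume.geometry))
    img.header.set_data_dtype(np.int16)
    nib.save(img, os.fspath(path))


def read_probability_volume(
    path_or_paths: str | os.PathLike | Sequence[str | os.PathLike],
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> ProbabilityVolume:
    """Read a probability volume from one 4D NIfTI or per-class 3D NIfTI files.

    A sequence of paths is interpreted as per-class files in schema code
    order; all files must share shape and spacing.
    """
    if isinstance(path_or_paths, (str, os.PathLike)):
        img = nib.load(Path(path_or_paths))
        disk = np.asanyarray(img.dataobj, dtype=np.float64)
        if disk.ndim != 4:
            raise ValueError(f"{path_or_paths}: expected a 4D NIfTI, got shape {disk.shape}")
        data = np.ascontiguousarray(disk.transpose(3, 2, 1, 0))
        return ProbabilityVolume(_geometry_from_img(img), data, schema)

    fields = []
    geom: VolumeGeometry | None = None
    for p in path_or_paths:
        img = nib.load(Path(p))
        g = _geometry_from_img(img)
        if geom is None:
            geom = g
        elif not geom.same_grid(g):
            raise GeometryMismatchError(f"{p} is on a different grid than the first class file")
        fields.append(np.asanyarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0))
    if geom is None or len(fields) != len(schema):
        raise ValueError(f"expected {len(schema)} class files, got {len(fields)}")
    return ProbabilityVolume(geom, np.stack(fields), schema)


def write_probability_volume(prob: ProbabilityVolume, path: str | os.PathLike) -> None:
    """Write a probability volume as a single 4D NIfTI (class as 4th axis)."""
    disk = np.ascontiguousarray(prob.data.transpose(3, 2, 1, 0))
    img = nib.Nifti1Image(disk.astype(np.float32), _affine(prob.geometry))
    nib.save(img, os.fspath(path))


def probability_class_paths(stem: str | os.PathLike, schema: LabelSchema = DEFAULT_SCHEMA) -> list[Path]:
    """Per-class file naming convention ``{stem}_class{code}.nii.gz``."""
    stem = os.fspath(stem)
    return [Path(f"{stem}_class{c}.nii.gz") for c in schema.sorted_codes]
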