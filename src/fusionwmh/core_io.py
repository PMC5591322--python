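"""Volumetric data model and readers/writers.

The package works in a fixed RAS+ world convention: x increases to the
subject's right, y to anterior, z to superior, all in millimetres.  Every
image is a :class:`Volume3D` carrying a voxel-index -> world-mm affine, so
left/right and anterior/posterior decisions elsewhere in the pipeline are
pure world-coordinate tests.

NIfTI-1 is the canonical on-disk format; DICOM series directories are
import-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import nibabel as nib
from scipy import ndimage

from ._exceptions import FormatError, ValidationError

Units = Literal["intensity", "counts", "mL/100g/min", "label"]

__all__ = [
    "Volume3D",
    "RigidTransform",
    "LabelMap",
    "DynamicSeries",
    "load_volume",
    "save_volume",
    "resample",
]


@dataclass
class Volume3D:
    """A 3D scalar grid with a voxel->world (mm) affine and a units tag.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar values on the grid.
    affine : ndarray, shape (4, 4)
        Maps homogeneous voxel indices to world mm (RAS+).
    units : {"intensity", "counts", "mL/100g/min", "label"}
    """

    voxels: np.ndarray
    affine: np.ndarray
    units: Units = "intensity"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError("voxels must be a 3D array with all dims >= 1")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        det = np.linalg.det(self.affine[:3, :3])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise ValidationError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """|det| of the 3x3 affine block: volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel indices (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World x, y, z of every voxel centre, each shaped like ``voxels``."""
        ii, jj, kk = np.meshgrid(
            *(np.arange(n) for n in self.shape), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        xyz = self.voxel_to_world(idx).reshape(*self.shape, 3)
        return xyz[..., 0], xyz[..., 1], xyz[..., 2]

    def like(self, voxels: np.ndarray, units: Units | None = None) -> "Volume3D":
        """New volume on this grid with different voxel data."""
        return Volume3D(voxels, self.affine.copy(), units or self.units)


@dataclass
class RigidTransform:
    """World-space rigid map p -> R p + t (mm).

    By package convention the transform used in :func:`resample` maps points
    in the *target* (fixed) world space into the *moving* world space, i.e.
    it is the pull-back used for interpolation.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValidationError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, angles_deg, translation_mm) -> "RigidTransform":
        """Rigid transform from intrinsic x-y-z Euler angles in degrees."""
        rx, ry, rz = np.deg2rad(np.asarray(angles_deg, dtype=float))
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(Rz @ Ry @ Rx, np.asarray(translation_mm, dtype=float))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class LabelMap:
    """Non-negative integer labels on a Volume3D grid; 0 is background."""

    labels: np.ndarray
    affine: np.ndarray
    lookup: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(np.mod(self.labels, 1) == 0):
                raise ValidationError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.lookup)
        if self.lookup and missing:
            raise ValidationError(f"labels missing from lookup: {sorted(missing)}")
        if not self.lookup:
            self.lookup = {int(v): f"label_{int(v)}" for v in sorted(present)}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def as_volume(self) -> Volume3D:
        return Volume3D(self.labels, self.affine, units="label")

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label (or any nonzero label)."""
        if label is None:
            return self.labels > 0
        return self.labels == label

    @classmethod
    def from_mask(cls, mask: np.ndarray, affine: np.ndarray,
                  name: str = "mask") -> "LabelMap":
        return cls(np.asarray(mask, dtype=bool).astype(np.int16), affine,
                   {1: name})


@dataclass
class DynamicSeries:
    """Ordered dynamic frames (2D or 3D count arrays) with frame times."""

    frames: np.ndarray          # (t, ...) stack
    frame_times: np.ndarray     # seconds from injection

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.shape[0] < 2:
            raise ValidationError("a dynamic series needs >= 2 frames")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValidationError("frame_times must match frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValidationError("counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def save_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI-1 (.nii or .nii.gz)."""
    data = vol.voxels
    if vol.units == "label":
        data = data.astype(np.int16)
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, os.fspath(path))


def load_volume(path: str | os.PathLike,
                format: Literal["nifti", "dicom_dir"] = "nifti",
                units: Units = "intensity") -> Volume3D:
    """Load a 3D volume from NIfTI or a DICOM series directory.

    The affine is taken from the file header and converted to RAS+ mm;
    voxel values are returned unchanged.
    """
    path = os.fspath(path)
    if format == "nifti":
        try:
            img = nib.load(path)
        except Exception as exc:  # nibabel raises several types here
            raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3D volume, got {data.shape}")
        affine = np.asarray(img.affine, dtype=float)
    elif format == "dicom_dir":
        data, affine = _read_dicom_series(path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError(f"{path}: non-invertible affine")
    return Volume3D(data, affine, units=units)


def _read_dicom_series(dirpath: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a single-series DICOM directory into (array, RAS+ affine)."""
    import pydicom

    files = sorted(
        os.path.join(dirpath, f) for f in os.listdir(dirpath)
        if not f.startswith(".")
    )
    if not files:
        raise FormatError(f"no files in DICOM directory {dirpath}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise FormatError(f"cannot read {f} as DICOM: {exc}") from exc
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no image slices in {dirpath}")

    def slice_pos(ds):
        ipp = np.array(ds.ImagePositionPatient, dtype=float)
        iop = np.array(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        return float(np.dot(ipp, normal))

    slices.sort(key=slice_pos)
    first = slices[0]
    rows, cols = int(first.Rows), int(first.Columns)
    arr = np.stack([s.pixel_array for s in slices], axis=-1)  # (row, col, slice)
    dr, dc = (float(x) for x in first.PixelSpacing)
    iop = np.array(first.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    if len(slices) > 1:
        p0 = np.array(slices[0].ImagePositionPatient, dtype=float)
        p1 = np.array(slices[1].ImagePositionPatient, dtype=float)
        slice_vec = p1 - p0
    else:
        thickness = float(getattr(first, "SliceThickness", 1.0))
        slice_vec = np.cross(row_dir, col_dir) * thickness
    origin = np.array(first.ImagePositionPatient, dtype=float)
    # DICOM pixel_array is (row, col); rows advance along col_dir, columns
    # along row_dir.  Build the LPS affine for (row, col, slice) indexing,
    # then flip to RAS+.
    aff = np.eye(4)
    aff[:3, 0] = col_dir * dr
    aff[:3, 1] = row_dir * dc
    aff[:3, 2] = slice_vec
    aff[:3, 3] = origin
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    return arr.astype(float), lps_to_ras @ aff


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(moving: Volume3D,
             target: Volume3D,
             transform: RigidTransform | None = None,
             interp: Literal["nearest", "trilinear"] = "trilinear",
             fill: float = 0.0) -> Volume3D:
    """Resample ``moving`` onto the grid of ``target``.

    ``transform`` maps target world coordinates into moving world
    coordinates (identity if None).  Label volumes must use nearest
    interpolation so no spurious label values are invented.
    """
    if transform is None:
        transform = RigidTransform.identity()
    if moving.units == "label" and interp != "nearest":
        raise ValidationError("label volumes require nearest interpolation")
    if interp not in ("nearest", "trilinear"):
        raise ValidationError(f"unknown interpolation {interp!r}")

    # voxel(target) -> world(target) -> world(moving) -> voxel(moving)
    full = np.linalg.inv(moving.affine) @ transform.matrix() @ target.affine
    matrix = full[:3, :3]
    offset = full[:3, 3]
    order = 0 if interp == "nearest" else 1
    out = ndimage.affine_transform(
        np.asarray(moving.voxels, dtype=float),
        matrix, offset=offset, output_shape=target.shape,
        order=order, mode="constant", cval=fill,
    )
    if moving.units == "label":
        out = np.round(out).astype(moving.voxels.dtype)
    return Volume3D(out, target.affine.copy(), units=moving.units)


def resample_labelmap(moving: LabelMap, target: Volume3D,
                      transform: RigidTransform | None = None) -> LabelMap:
    """Nearest-neighbour resampling of a label map onto a target grid."""
    vol = resample(moving.as_volume(), target, transform, interp="nearest")
    return LabelMap(vol.voxels.astype(moving.labels.dtype), target.affine.copy(),
                    dict(moving.lookup))


def reorient_to_canonical(vol: Volume3D) -> Volume3D:
    """Reorder axes/flips so the affine is closest to diagonal RAS+.

    World coordinates of every voxel centre are preserved exactly.
    """
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=float), vol.affine)
    can = nib.as_closest_canonical(img)
    return Volume3D(np.asanyarray(can.dataobj), np.asarray(can.affine),
                    units=vol.units)
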