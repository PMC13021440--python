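"""Volume and mask I/O plus the coordinate conventions shared by the whole pipeline.

Every array in this package is indexed ``(z, y, x)``:

* axis 0 — Z, superior–inferior: the axial slice index,
* axis 1 — Y, anterior–posterior, with the anterior side at *lower* index
  (the skin sits near ``y = 0``),
* axis 2 — X, left–right.

Voxel indices are 0-based; physical coordinates are millimetres.  Readers
reorient on load so downstream code never sees another axis order.  Direction
matrices that are not pure axis permutations/flips are rejected rather than
resampled — resampling would silently alter every length measured later.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Geometry",
    "Volume",
    "Mask",
    "VoxelPoint",
    "OrientationError",
    "read_volume",
    "write_volume",
    "read_mask",
    "voxel_to_world",
    "world_to_voxel",
    "read_landmark",
    "write_landmark",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


class OrientationError(ValueError):
    """Raised for direction matrices that are not axis permutations/flips."""


@dataclass(frozen=True)
class Geometry:
    """Grid shape, spacing and origin, all in (z, y, x) order, mm units."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Geometry fields must be triples (z, y, x)")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape components must be >= 1, got {self.shape}")
        if any(not (float(s) > 0) for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))


@dataclass(frozen=True)
class VoxelPoint:
    """0-based voxel index (z, y, x)."""

    z: int
    y: int
    x: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)

    def in_bounds(self, g: Geometry) -> bool:
        return all(0 <= c < n for c, n in zip(self.as_tuple(), g.shape))


@dataclass
class Volume:
    """A 3D scalar grid (HU-like intensities) with its geometry."""

    geometry: Geometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass
class Mask:
    """A binary grid sharing the Volume conventions; values are 0/1 uint8."""

    geometry: Geometry
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {arr.shape} != geometry shape {self.geometry.shape}"
            )
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        self.values = arr.astype(np.uint8, copy=False)

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


def voxel_to_world(p: VoxelPoint, g: Geometry) -> tuple[float, float, float]:
    """Physical (z, y, x) mm coordinates of a voxel centre."""
    if not p.in_bounds(g):
        raise IndexError(f"voxel {p.as_tuple()} outside grid of shape {g.shape}")
    return tuple(c * s + o for c, s, o in zip(p.as_tuple(), g.spacing, g.origin))


def world_to_voxel(point_mm: Sequence[float], g: Geometry) -> VoxelPoint:
    """Nearest voxel to a physical point; exact inverse of voxel_to_world on lattice points."""
    idx = [round((c - o) / s) for c, s, o in zip(point_mm, g.spacing, g.origin)]
    p = VoxelPoint(*(int(i) for i in idx))
    if not p.in_bounds(g):
        raise IndexError(f"point {tuple(point_mm)} maps outside grid of shape {g.shape}")
    return p


def points_to_world(points: np.ndarray, g: Geometry) -> np.ndarray:
    """Vectorised voxel→mm conversion for an (n, 3) array of (z, y, x) indices."""
    pts = np.asarray(points, dtype=float)
    return pts * np.asarray(g.spacing) + np.asarray(g.origin)


# ---------------------------------------------------------------------------
# Orientation handling
# ---------------------------------------------------------------------------

def _signed_permutation(direction: np.ndarray, tol: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a 3x3 direction matrix into (world axis per image axis, signs).

    Columns of ``direction`` are the world-space (x, y, z) unit vectors of the
    image axes.  Anything that is not a permutation with flips is rejected.
    """
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise OrientationError(f"direction must be 3x3, got {d.shape}")
    axes = np.full(3, -1, dtype=int)
    signs = np.zeros(3)
    for img_ax in range(3):
        col = d[:, img_ax]
        w = int(np.argmax(np.abs(col)))
        if abs(abs(col[w]) - 1.0) > tol or np.any(np.abs(np.delete(col, w)) > tol):
            raise OrientationError(
                "direction matrix is not an axis permutation/flip; "
                "resample the image externally before loading"
            )
        axes[img_ax] = w
        signs[img_ax] = np.sign(col[w])
    if sorted(axes.tolist()) != [0, 1, 2]:
        raise OrientationError("direction matrix columns do not span distinct axes")
    return axes, signs


def _reorient_to_zyx(
    arr_ijk: np.ndarray,
    direction: np.ndarray,
    spacing_ijk: Sequence[float],
    origin_xyz: Sequence[float],
) -> tuple[np.ndarray, Geometry]:
    """Reorder an image-axis-ordered array to the package's (z, y, x) layout.

    ``arr_ijk`` has axes in image order (i fastest-varying world direction
    first); ``direction`` columns map image axes to world (x, y, z).
    """
    axes, signs = _signed_permutation(direction)
    spacing_ijk = np.asarray(spacing_ijk, dtype=float)
    origin_xyz = np.asarray(origin_xyz, dtype=float)

    # Image axis serving each world axis, in world order (x, y, z).
    img_for_world = np.array([int(np.where(axes == w)[0][0]) for w in range(3)])

    # Output axes are (z, y, x) == world axes (2, 1, 0).
    order = [img_for_world[2], img_for_world[1], img_for_world[0]]
    out = np.transpose(arr_ijk, order)
    spacing_zyx = [float(spacing_ijk[i]) for i in order]

    # World coordinate of the voxel that ends up at index (0,0,0): start from
    # the original origin and walk to the far corner along flipped axes.
    corner = origin_xyz.copy()
    for img_ax in range(3):
        if signs[img_ax] < 0:
            n = arr_ijk.shape[img_ax]
            corner[axes[img_ax]] += signs[img_ax] * spacing_ijk[img_ax] * (n - 1)
    for out_ax, img_ax in enumerate(order):
        if signs[img_ax] < 0:
            out = np.flip(out, axis=out_ax)
    origin_zyx = (float(corner[2]), float(corner[1]), float(corner[0]))
    geom = Geometry(shape=tuple(out.shape), spacing=tuple(spacing_zyx), origin=origin_zyx)
    return np.ascontiguousarray(out), geom


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _check_nrrd_has_spacing(path: Path) -> None:
    # SimpleITK silently substitutes unit spacing; refuse that default here.
    with open(path, "rb") as fh:
        header = fh.read(8192).decode("ascii", errors="replace")
    fields = {
        line.split(":", 1)[0].strip().lower()
        for line in header.splitlines()
        if ":" in line
    }
    if not fields & {"space directions", "spacings", "axis mins"}:
        raise ValueError(f"{path}: NRRD header carries no voxel spacing; refusing a silent 1 mm default")


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NRRD or NIfTI volume, reoriented to (z, y, x)."""
    arr, geom = _read_array(Path(path))
    return Volume(geometry=geom, values=arr)


def read_mask(path: str | os.PathLike) -> Mask:
    """Read a binary mask; values must be 0/1 after loading."""
    arr, geom = _read_array(Path(path))
    return Mask(geometry=geom, values=arr.astype(np.uint8))


def _read_array(path: Path) -> tuple[np.ndarray, Geometry]:
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3 spatial dimensions, got {data.ndim}")
        affine = np.asarray(img.affine, dtype=float)
        m = affine[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        if np.any(spacing <= 0):
            raise ValueError(f"{path}: NIfTI affine has a zero-length axis")
        direction = m / spacing
        return _reorient_to_zyx(data, direction, spacing, affine[:3, 3])

    _check_nrrd_has_spacing(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - sitk error text varies
        raise IOError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected 3 spatial dimensions, got {img.GetDimension()}")
    # GetArrayFromImage yields (k, j, i); transpose back to image order (i, j, k).
    arr_ijk = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return _reorient_to_zyx(arr_ijk, direction, img.GetSpacing(), img.GetOrigin())


def write_volume(volume: Volume | Mask, path: str | os.PathLike) -> None:
    """Write a volume (float32) or mask (uint8) as NRRD or NIfTI.

    Files round-trip through :func:`read_volume` / :func:`read_mask` with
    bit-identical values and equal geometry.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    arr = volume.values
    dtype = np.uint8 if isinstance(volume, Mask) else np.float32
    arr = arr.astype(dtype, copy=False)
    g = volume.geometry
    spacing_xyz = (g.spacing[2], g.spacing[1], g.spacing[0])
    origin_xyz = (g.origin[2], g.origin[1], g.origin[0])

    if _is_nifti(path):
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = spacing_xyz
        affine[:3, 3] = origin_xyz
        # nibabel expects (x, y, z) data order.
        nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.transpose(2, 1, 0)), affine), str(path))
        return

    img = sitk.GetImageFromArray(arr)  # (z, y, x) in → sitk image
    img.SetSpacing(spacing_xyz)
    img.SetOrigin(origin_xyz)
    try:
        sitk.WriteImage(img, str(path), useCompression=False)
    except RuntimeError as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmark(path: str | os.PathLike) -> VoxelPoint:
    """Read a JSON landmark record ``{"z": .., "y": .., "x": ..}``."""
    with open(path) as fh:
        rec = json.load(fh)
    return VoxelPoint(z=int(rec["z"]), y=int(rec["y"]), x=int(rec["x"]))


def write_landmark(p: VoxelPoint, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({"z": p.z, "y": p.y, "x": p.x}, fh)
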