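"""NIfTI-1 volume and mask I/O with grid-alignment contracts.

Volumes are plain 3-D scalar grids with per-axis voxel spacings in
millimetres.  Orientation and affine rotation are deliberately ignored:
every quantity computed downstream is a volume (voxel count times voxel
size), which is rotation invariant.  The T1-contrast and T2-FLAIR series
of a patient are *not* required to share a grid — compartment volumes are
measured per series and combined as scalars — but every mask must align
exactly with the grid of its own reference image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import GridMismatchError, VolumeFormatError

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_from_array",
]


@dataclass(eq=False)
class ImageVolume:
    """A 3-D scalar image with physical voxel spacings.

    Parameters
    ----------
    grid
        3-D array of finite intensities (arbitrary units).
    voxel_dims
        Per-axis voxel spacing in mm; all entries must be positive.
    id
        Opaque identifier, used to bind masks to their reference image.
    """

    grid: np.ndarray
    voxel_dims: tuple[float, float, float]
    id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3:
            raise VolumeFormatError(
                f"ImageVolume requires 3-D data, got {grid.ndim}-D with shape {grid.shape}"
            )
        if not np.all(np.isfinite(grid)):
            raise VolumeFormatError("ImageVolume grid contains non-finite values")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise VolumeFormatError(f"voxel_dims must be three positive lengths, got {dims}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "voxel_dims", dims)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))


@dataclass(eq=False)
class MaskVolume:
    """A binary mask on the grid of a reference :class:`ImageVolume`."""

    grid: np.ndarray
    reference_id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise VolumeFormatError(
                f"MaskVolume requires 3-D data, got {grid.ndim}-D with shape {grid.shape}"
            )
        values = np.unique(grid)
        if not np.all(np.isin(values, (0, 1))):
            raise VolumeFormatError(
                f"MaskVolume values must be exactly 0 or 1, found {values[:10]}"
            )
        object.__setattr__(self, "grid", grid.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Number of voxels set in the mask."""
        return int(self.grid.sum())

    def bound_to(self, reference: ImageVolume) -> "MaskVolume":
        """Return a copy bound to ``reference``, checking grid alignment."""
        if self.shape != reference.shape:
            raise GridMismatchError(
                f"mask shape {self.shape} does not match reference "
                f"'{reference.id}' shape {reference.shape}"
            )
        return MaskVolume(self.grid, reference_id=reference.id)


def _load_array(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
    except VolumeFormatError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    return data, tuple(float(z) for z in zooms)


def read_volume(path: str | Path, id: str | None = None) -> ImageVolume:
    """Read a 3-D scalar volume from a NIfTI-1 file.

    Voxel dimensions are taken from the header spacings (``pixdim``);
    the rotational part of the affine is ignored.
    """
    data, zooms = _load_array(path)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D data with shape {data.shape}"
        )
    if id is None:
        id = Path(path).name.removesuffix(".gz").removesuffix(".nii")
    return ImageVolume(grid=data, voxel_dims=zooms[:3], id=id)


def write_volume(path: str | Path, volume: ImageVolume) -> None:
    """Write an :class:`ImageVolume` to NIfTI-1 with a diagonal affine."""
    affine = np.diag(list(volume.voxel_dims) + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_dims)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: ImageVolume) -> MaskVolume:
    """Read a binary mask and bind it to its reference image.

    Nonzero values are coerced to 1 (labelled-mask dialects are common);
    a warning is emitted when coercion occurs.  The grid shape must match
    the reference exactly.
    """
    data, _ = _load_array(path)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D mask, got {data.ndim}-D data with shape {data.shape}"
        )
    if data.shape != reference.shape:
        raise GridMismatchError(
            f"{path}: mask shape {data.shape} does not match reference "
            f"'{reference.id}' shape {reference.shape}"
        )
    return mask_from_array(data, reference, source=str(path))


def mask_from_array(
    data: np.ndarray, reference: ImageVolume, source: str = "<array>"
) -> MaskVolume:
    """Build a mask from an arbitrary numeric array, coercing nonzero to 1."""
    data = np.asarray(data)
    if data.shape != reference.shape:
        raise GridMismatchError(
            f"{source}: mask shape {data.shape} does not match reference "
            f"'{reference.id}' shape {reference.shape}"
        )
    binary = (data != 0).astype(np.uint8)
    if not np.array_equal(binary, data):
        warnings.warn(
            f"{source}: mask contains values other than 0/1; nonzero coerced to 1",
            UserWarning,
            stacklevel=2,
        )
    return MaskVolume(grid=binary, reference_id=reference.id)


def write_mask(path: str | Path, mask: MaskVolume, voxel_dims: tuple[float, float, float]) -> None:
    """Write a mask as an integer NIfTI volume with the given spacings."""
    affine = np.diag(list(voxel_dims) + [1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(voxel_dims)
    nib.save(img, str(path))
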