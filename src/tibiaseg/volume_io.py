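"""MetaImage (MHD) volume I/O, geometry, and slice-stack conversion.

Volumes are stored as numpy arrays whose axis order matches the MHD header's
``DimSize`` (axis 0 = first header dimension).  For the reference murine tibia
geometry of 128 x 64 x 256 voxels at 0.09 x 0.075 x 0.094 mm, axis 1 (size 64)
is the coronal slicing axis and each coronal slice is a 128 x 256 image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGeometry",
    "ScanVolume",
    "BinaryMask",
    "SliceStack",
    "read_mhd",
    "write_mhd",
    "extract_coronal_slices",
    "restack_slices",
    "mask_volume_mm3",
    "CORONAL_AXIS",
]

#: Default coronal slicing axis for the reference 128 x 64 x 256 layout.
CORONAL_AXIS = 1

#: Intensity ceiling implied by the scanner's 14-bit grayscale depth.
MAX_INTENSITY_14BIT = 2**14 - 1


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid dimensions and physical spacing (mm per voxel per axis)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3:
            raise ValueError("geometry requires 3 dims and 3 spacings")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(not (s > 0) for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (product of the three spacings)."""
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


#: The reference scan geometry of the murine tibia protocol.
REFERENCE_GEOMETRY = VolumeGeometry(
    dims=(128, 64, 256), spacing=(0.09, 0.075, 0.094)
)


@dataclass
class ScanVolume:
    """A 3D grayscale MRI volume with its geometry."""

    geometry: VolumeGeometry
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.shape != self.geometry.dims:
            raise ValueError(
                f"intensity grid shape {self.intensities.shape} does not match "
                f"geometry dims {self.geometry.dims}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class BinaryMask:
    """A 3D {0,1} label grid aligned to a scan volume."""

    geometry: VolumeGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.geometry.dims:
            raise ValueError(
                f"label grid shape {self.labels.shape} does not match "
                f"geometry dims {self.geometry.dims}"
            )
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())


@dataclass
class SliceStack:
    """An ordered stack of 2D slices extracted from a 3D volume."""

    slices: np.ndarray  # (n_slices, height, width)
    slice_axis: int
    geometry: VolumeGeometry
    is_mask: bool = field(default=False)

    def __len__(self) -> int:
        return self.slices.shape[0]


def _to_sitk(vol: ScanVolume | BinaryMask) -> sitk.Image:
    if isinstance(vol, BinaryMask):
        arr = vol.labels.astype(np.uint8)
    else:
        arr = vol.intensities
        if not np.all(np.isfinite(arr)):
            raise ValueError("refusing to write non-finite intensities")
    # SimpleITK array layout is (z, y, x); ours is (x, y, z) header order.
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.geometry.spacing))
    img.SetOrigin(tuple(vol.geometry.origin))
    return img


def write_mhd(vol: ScanVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as an MHD header + raw pair.

    Masks are stored as unsigned 8-bit {0,1}; grayscale volumes keep their
    array dtype (the phantom generator emits unsigned 16-bit).
    """
    path = Path(path)
    if path.suffix.lower() != ".mhd":
        raise ValueError(f"expected a .mhd path, got {path}")
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    sitk.WriteImage(_to_sitk(vol), str(path))


def read_mhd(path: str | Path, as_mask: bool | None = None) -> ScanVolume | BinaryMask:
    """Read an MHD volume; returns a :class:`BinaryMask` if the data is a
    {0,1}-valued 8-bit grid (or ``as_mask=True``), else a :class:`ScanVolume`.

    Any nonzero value in a mask read is coerced to 1 with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such MetaImage header: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps missing .raw / bad headers
        raise IOError(f"failed to read MetaImage {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    geom = VolumeGeometry(
        dims=arr.shape,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
    if as_mask is None:
        as_mask = arr.dtype == np.uint8
    if as_mask:
        if not np.isin(arr, (0, 1)).all():
            warnings.warn(
                f"mask {path.name} contains values outside {{0,1}}; coercing "
                "nonzero to 1",
                stacklevel=2,
            )
            arr = (arr != 0).astype(np.uint8)
        return BinaryMask(geometry=geom, labels=arr)
    return ScanVolume(geometry=geom, intensities=arr)


def extract_coronal_slices(
    vol: ScanVolume | BinaryMask, slice_axis: int = CORONAL_AXIS
) -> SliceStack:
    """Split a 3D volume into ordered 2D slices along the coronal axis.

    With the reference layout, slicing along axis 1 yields 64 slices of
    128 x 256 per scan.
    """
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    is_mask = isinstance(vol, BinaryMask)
    arr = vol.labels if is_mask else vol.intensities
    slices = np.moveaxis(arr, slice_axis, 0)
    return SliceStack(
        slices=slices,
        slice_axis=slice_axis,
        geometry=vol.geometry,
        is_mask=is_mask,
    )


def restack_slices(stack: SliceStack) -> ScanVolume | BinaryMask:
    """Inverse of :func:`extract_coronal_slices`: reassemble the 3D volume."""
    arr = np.moveaxis(stack.slices, 0, stack.slice_axis)
    if stack.is_mask:
        return BinaryMask(geometry=stack.geometry, labels=arr)
    return ScanVolume(geometry=stack.geometry, intensities=arr)


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Physical mask volume: set-voxel count times the voxel volume (mm^3)."""
    return mask.voxel_count * mask.geometry.voxel_volume
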