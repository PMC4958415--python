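"""CT volume container and NIfTI-1 / MetaImage I/O.

Conventions
-----------
* ``data`` is indexed ``[i, j, k]`` along the world x/y/z-ish axes with the
  direction matrix mapping index axes to world axes.
* Voxel index ``(0, 0, 0)`` is the *center* of the corner voxel; indices
  are 0-based and may be fractional (subvoxel positions).
* ``world = origin + direction @ (index * spacing)`` with everything in mm.
* NIfTI qform/sform conflicts are resolved by preferring the sform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import ValidationError, VolumeFormatError

NIFTI_SUFFIXES = (".nii", ".nii.gz")
METAIMAGE_SUFFIXES = (".mha", ".mhd")


@dataclass
class VoxelVolume:
    """A scalar CT attenuation grid (HU) with world geometry."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValidationError(f"volume needs >= 2 voxels per axis, got {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        _validate_direction(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def voxel_to_world(self, index) -> np.ndarray:
        """Map (fractional, 0-based) voxel indices to world mm."""
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_voxel(self, world) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world`."""
        pts = np.asarray(world, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing


def _validate_direction(direction: np.ndarray) -> None:
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
        raise ValidationError("direction matrix is not orthonormal")
    if np.linalg.det(direction) < 0:
        raise ValidationError("direction matrix determinant must be +1")


def voxel_to_world(volume: VoxelVolume, index) -> np.ndarray:
    return volume.voxel_to_world(index)


def world_to_voxel(volume: VoxelVolume, world) -> np.ndarray:
    return volume.world_to_voxel(world)


def _affine_from_geometry(volume: VoxelVolume) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = volume.direction @ np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    return affine


def _geometry_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise ValidationError("affine has a zero-length column")
    direction = linear / spacing
    return spacing, affine[:3, 3].copy(), direction


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"volume file does not exist: {path}")
    name = path.name.lower()
    try:
        if name.endswith(NIFTI_SUFFIXES):
            return _read_nifti(path)
        if name.endswith(METAIMAGE_SUFFIXES):
            return _read_metaimage(path)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap reader internals
        raise VolumeFormatError(f"could not read volume {path}: {exc}") from exc
    raise VolumeFormatError(
        f"unsupported volume format for {path}; expected one of "
        f"{NIFTI_SUFFIXES + METAIMAGE_SUFFIXES}"
    )


def _read_nifti(path: Path) -> VoxelVolume:
    img = nib.load(path)
    sform, scode = img.get_sform(coded=True)
    affine = sform if scode else img.affine
    data = np.asanyarray(img.dataobj)  # forces the (possibly truncated) read
    spacing, origin, direction = _geometry_from_affine(np.asarray(affine))
    _validate_direction(direction)
    return VoxelVolume(data=data, spacing=spacing, origin=origin, direction=direction)


def _read_metaimage(path: Path) -> VoxelVolume:
    img = sitk.ReadImage(str(path))
    # SimpleITK arrays are indexed [z, y, x]; transpose to [x, y, z]
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    _validate_direction(direction)
    return VoxelVolume(
        data=data,
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
        direction=direction,
    )


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume; format chosen from the file suffix."""
    path = Path(path)
    name = path.name.lower()
    try:
        if name.endswith(NIFTI_SUFFIXES):
            affine = _affine_from_geometry(volume)
            img = nib.Nifti1Image(volume.data, affine)
            img.set_sform(affine, code=1)
            img.set_qform(affine, code=1)
            nib.save(img, path)
            return
        if name.endswith(METAIMAGE_SUFFIXES):
            img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
            img.SetSpacing(tuple(volume.spacing))
            img.SetOrigin(tuple(volume.origin))
            img.SetDirection(tuple(volume.direction.ravel()))
            sitk.WriteImage(img, str(path))
            return
    except OSError as exc:
        raise VolumeFormatError(f"could not write volume {path}: {exc}") from exc
    except RuntimeError as exc:
        raise VolumeFormatError(f"could not write volume {path}: {exc}") from exc
    raise VolumeFormatError(
        f"unsupported volume format for {path}; expected one of "
        f"{NIFTI_SUFFIXES + METAIMAGE_SUFFIXES}"
    )
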