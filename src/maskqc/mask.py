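"""The :class:`BrainMask` container and NIfTI I/O.

A brain mask is a 3D binary volume marking brain-tissue voxels, the output of a
skull-stripping (brain-extraction) step. Physical voxel spacing (mm) travels
with the voxel grid because every physical-unit feature and distance depends on
it. Any voxel value > 0 is treated as foreground, so masks saved as 0/255 or as
floats load correctly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import nibabel as nib
import numpy as np

from .errors import ConfigError, DataError

__all__ = ["BrainMask", "load_mask", "save_mask", "iter_mask_dir"]

NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass(frozen=True)
class BrainMask:
    """A 3D binary segmentation mask with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array; any value > 0 is foreground. Stored as ``bool``.
    spacing
        Per-axis physical voxel size in mm; all components strictly positive.
    identifier
        Opaque string naming the mask (file stem, cohort id, ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ConfigError(f"mask must be 3D, got shape {vox.shape}")
        object.__setattr__(self, "voxels", vox > 0)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ConfigError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def with_voxels(self, voxels: np.ndarray, identifier: str | None = None) -> "BrainMask":
        return BrainMask(voxels, self.spacing, self.identifier if identifier is None else identifier)


def load_mask(path: str | os.PathLike, identifier: str | None = None) -> BrainMask:
    """Read a NIfTI mask; spacing comes from the header zooms."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise DataError(f"cannot read mask {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if identifier is None:
        identifier = path.name
        for suf in NIFTI_SUFFIXES:
            if identifier.endswith(suf):
                identifier = identifier[: -len(suf)]
                break
    return BrainMask(data, spacing, identifier)


def save_mask(mask: BrainMask, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI with a diagonal affine built from spacing."""
    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def iter_mask_dir(directory: str | os.PathLike) -> Iterator[BrainMask]:
    """Yield masks from every ``.nii``/``.nii.gz`` file in a directory, sorted by name."""
    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"not a directory: {directory}")
    for path in sorted(directory.iterdir()):
        if path.name.endswith(NIFTI_SUFFIXES):
            yield load_mask(path)
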