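"""Read/write CT volumes and organ masks as NIfTI-1 or MetaImage.

SimpleITK does the heavy lifting; arrays are converted between its (z, y, x)
index order and this package's (x, y, z) convention.  World coordinates are
millimetres, LPS, with an identity direction matrix.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .phantom import CTVolume, OrganMaskSet, STRUCTURES

__all__ = ["read_volume", "write_volume", "read_masks", "write_masks"]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_extension(path: str | os.PathLike) -> None:
    name = str(path).lower()
    if not name.endswith(_EXTENSIONS):
        raise ValueError(
            f"unsupported image format for {path!r}; expected one of {_EXTENSIONS}"
        )


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | os.PathLike) -> CTVolume:
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return CTVolume(voxels=arr, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def write_masks(masks: OrganMaskSet, directory: str | os.PathLike,
                prefix: str = "mask", fmt: str = ".nii.gz") -> dict[str, Path]:
    """Write one file per structure; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, mask in masks.items():
        p = directory / f"{prefix}_{name}{fmt}"
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(mask.transpose(2, 1, 0).astype(np.uint8))
        )
        sitk.WriteImage(img, str(p))
        paths[name] = p
    return paths


def read_masks(paths: dict[str, str | os.PathLike], reference: CTVolume | None = None
               ) -> OrganMaskSet:
    """Load the five structure masks from ``{structure: path}``.

    If ``reference`` is given, each mask's shape must match its grid.
    """
    missing = [s for s in STRUCTURES if s not in paths]
    if missing:
        raise ValueError(f"missing mask path(s) for structure(s): {', '.join(missing)}")
    arrays = {}
    for name in STRUCTURES:
        _check_extension(paths[name])
        img = sitk.ReadImage(str(paths[name]))
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(bool)
        if reference is not None and arr.shape != reference.shape:
            raise ValueError(
                f"mask '{name}' shape {arr.shape} does not match volume shape "
                f"{reference.shape}"
            )
        arrays[name] = arr
    return OrganMaskSet(**arrays)
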