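"""NIfTI and tabular I/O for DCE series, masks and measures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .kinetics import DCESeries, SegmentationMasks

__all__ = [
    "affine_from_spacing",
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
]


def affine_from_spacing(voxel_spacing_mm: Sequence[float]) -> np.ndarray:
    """Axis-aligned affine with the given voxel spacing (mm)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_spacing_mm
    return aff


def save_series(series: DCESeries, out: str | Path, single_4d: bool = True) -> list[Path]:
    """Write a DCE series as NIfTI-1.

    With ``single_4d`` the four volumes go to one 4D file ``out``; otherwise
    ``out`` is treated as a directory receiving ``t0.nii.gz .. t3.nii.gz``.
    Returns the written paths.
    """
    aff = affine_from_spacing(series.voxel_spacing_mm)
    out = Path(out)
    if single_4d:
        data = np.moveaxis(series.signal, 0, -1)  # x,y,z,t
        img = nib.Nifti1Image(data, aff)
        img.header.set_zooms(tuple(series.voxel_spacing_mm) + (1.0,))
        nib.save(img, out)
        return [out]
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(4):
        p = out / f"t{k}.nii.gz"
        nib.save(nib.Nifti1Image(series.signal[k], aff), p)
        paths.append(p)
    return paths


def _check_affines(affines: list[np.ndarray]) -> None:
    for a in affines[1:]:
        if not np.allclose(a, affines[0], atol=1e-4):
            raise ValueError("volumes are not on a consistent grid (affines differ)")


def load_series(
    paths: Sequence[str | Path] | str | Path,
    times_min: Sequence[float],
) -> DCESeries:
    """Load a DCE series from one 4D NIfTI or four 3D NIfTI files."""
    times = np.asarray(times_min, dtype=float)
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 4 or data.shape[-1] != 4:
            raise ValueError("4D series file must hold exactly four volumes")
        signal = np.moveaxis(data, -1, 0)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        return DCESeries(signal=signal, times_min=times, voxel_spacing_mm=spacing)
    imgs = [nib.load(str(p)) for p in paths]
    if len(imgs) != 4:
        raise ValueError("need exactly four volumes (pre + three post)")
    _check_affines([i.affine for i in imgs])
    signal = np.stack([np.asarray(i.get_fdata(), dtype=float) for i in imgs])
    spacing = np.asarray(imgs[0].header.get_zooms()[:3], dtype=float)
    return DCESeries(signal=signal, times_min=times, voxel_spacing_mm=spacing)


def save_mask(mask: np.ndarray, voxel_spacing_mm: Sequence[float], path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8), affine_from_spacing(voxel_spacing_mm)
    )
    nib.save(img, path)
    return path


def load_mask(path: str | Path, grid_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if grid_shape is not None and data.shape != tuple(grid_shape):
        raise ValueError(f"mask grid {data.shape} does not match series grid {grid_shape}")
    return data > 0.5


def load_masks(
    breast_path: str | Path, fgt_path: str | Path, grid_shape: tuple[int, int, int]
) -> SegmentationMasks:
    return SegmentationMasks(
        breast=load_mask(breast_path, grid_shape), fgt=load_mask(fgt_path, grid_shape)
    )
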