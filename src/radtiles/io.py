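"""Reading and writing the pipeline's file formats.

Volumes and masks travel as NIfTI (via nibabel) or NRRD (via SimpleITK),
selected by file extension; feature matrices, grid maps and outcome tables
as CSV; models and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .features.preprocess import ROIMask, VoxelVolume

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "read_feature_csv",
    "write_feature_csv",
]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_volume(volume: VoxelVolume, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        # nibabel uses (x, y, z) axis order; our arrays are (z, y, x)
        affine = np.diag(list(volume.spacing_mm[::-1]) + [1.0])
        nib.save(nib.Nifti1Image(volume.intensities.T, affine), path)
    else:
        img = sitk.GetImageFromArray(volume.intensities)
        img.SetSpacing(tuple(volume.spacing_mm[::-1]))
        sitk.WriteImage(img, str(path))


def write_mask(mask: ROIMask, volume: VoxelVolume, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag(list(volume.spacing_mm[::-1]) + [1.0])
        nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8).T, affine), path)
    else:
        img = sitk.GetImageFromArray(mask.mask.astype(np.uint8))
        img.SetSpacing(tuple(volume.spacing_mm[::-1]))
        sitk.WriteImage(img, str(path))


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64).T  # back to (z, y, x)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3][::-1])
        return VoxelVolume(data, spacing)
    img = sitk.ReadImage(str(path))
    return VoxelVolume(sitk.GetArrayFromImage(img).astype(np.float64), img.GetSpacing()[::-1])


def read_mask(path) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(vol.intensities > 0.5)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))


def read_json(path):
    return json.loads(Path(path).read_text())
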