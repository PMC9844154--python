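"""Volume containers, isotropic resampling and gray-level discretization.

Texture matrices (GLCM, GLSZM) are computed on a gray-level-discretized ROI;
both resampling and binning are recorded in the extraction manifest because
texture values depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelVolume",
    "ROIMask",
    "DiscretizedROI",
    "resample_isotropic",
    "discretize",
]


@dataclass
class VoxelVolume:
    """3D attenuation array (HU) with physical voxel spacing in mm.

    Axis order is (z, y, x); ``spacing_mm`` follows the same order.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be a positive triple")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ROIMask:
    """Binary mask aligned to a VoxelVolume (same shape, >= 1 voxel set)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DiscretizedROI:
    """Gray levels 1..Ng on each masked voxel; 0 outside the mask.

    ``n_levels`` is the nominal Ng of the binning scheme; the realized
    number of occupied levels can be smaller.
    """

    levels: np.ndarray  # int array, full volume shape, 0 = outside mask
    mask: np.ndarray
    n_levels: int
    binning: dict = field(default_factory=dict)

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _to_sitk(arr: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(arr)
    # SimpleITK spacing is (x, y, z); our arrays are (z, y, x)
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    return img


def resample_isotropic(
    volume: VoxelVolume,
    mask: ROIMask,
    target_spacing: float = 1.0,
) -> tuple[VoxelVolume, ROIMask]:
    """Resample volume and mask to isotropic spacing.

    Intensities are interpolated trilinearly, the mask nearest-neighbour.
    Already-isotropic input at the target spacing is returned unchanged.

    Raises
    ------
    ValueError
        If the mask vanishes after resampling (degenerate ROI).
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    if all(abs(s - target_spacing) < 1e-12 for s in volume.spacing_mm):
        return volume, mask

    img = _to_sitk(volume.intensities, volume.spacing_mm)
    mimg = _to_sitk(mask.mask.astype(np.uint8), volume.spacing_mm)
    new_size = [
        max(1, int(round(n * s / target_spacing)))
        for n, s in zip(img.GetSize(), img.GetSpacing())
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target_spacing,) * 3)
    res.SetSize(new_size)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkLinear)
    out_img = res.Execute(img)
    res.SetInterpolator(sitk.sitkNearestNeighbor)
    out_mask = res.Execute(mimg)

    new_mask = sitk.GetArrayFromImage(out_mask).astype(bool)
    if not new_mask.any():
        raise ValueError("ROI vanished after resampling (degenerate ROI)")
    new_vol = VoxelVolume(
        sitk.GetArrayFromImage(out_img),
        (target_spacing,) * 3,
        origin=volume.origin,
    )
    return new_vol, ROIMask(new_mask)


def discretize(
    volume: VoxelVolume,
    mask: ROIMask,
    bin_count: int | None = 32,
    bin_width: float | None = None,
) -> DiscretizedROI:
    """Discretize masked intensities to integer gray levels 1..Ng.

    Fixed-bin-count (default 32) divides the masked intensity range into
    ``bin_count`` equal bins; fixed-bin-width uses bins of ``bin_width`` HU
    anchored at the masked minimum.  level = 1 + floor((x - min)/width),
    capped at Ng.  A zero intensity range yields a single level 1.
    """
    if (bin_count is None) == (bin_width is None):
        raise ValueError("specify exactly one of bin_count / bin_width")
    x = volume.intensities[mask.mask]
    lo, hi = float(x.min()), float(x.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    if hi == lo:
        levels[mask.mask] = 1
        ng = 1 if bin_count is None else int(bin_count)
        scheme = {"scheme": "degenerate", "n_levels": ng}
        return DiscretizedROI(levels, mask.mask, ng, scheme)
    if bin_count is not None:
        ng = int(bin_count)
        if ng < 1:
            raise ValueError("bin_count must be >= 1")
        width = (hi - lo) / ng
        scheme = {"scheme": "fixed_bin_count", "bin_count": ng, "bin_width": width}
    else:
        width = float(bin_width)
        if width <= 0:
            raise ValueError("bin_width must be > 0")
        ng = 1 + int(np.floor((hi - lo) / width))
        scheme = {"scheme": "fixed_bin_width", "bin_width": width, "bin_count": ng}
    lv = 1 + np.floor((x - lo) / width).astype(np.int64)
    np.clip(lv, 1, ng, out=lv)
    levels[mask.mask] = lv
    return DiscretizedROI(levels, mask.mask, ng, scheme)
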