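"""Gray-level size-zone matrix (GLSZM) and its 16 texture features.

A zone is a connected component of masked voxels sharing the same discretized
gray level.  P(i, j) counts zones of gray level i and size j; texture summaries
of P emphasize the preponderance of large/small and low/high-gray zones.  The
model features GLV (gray level variance) and LALGLE (large area low gray level
emphasis) both live here:

    GLV    = sum_ij p(i,j) (i - mu)^2,        p = P / Nz,  mu = sum_ij i p(i,j)
    LALGLE = (1/Nz) sum_ij P(i,j) j^2 / i^2

Zone connectivity is 26-neighbour in 3D by default (faces, edges and corners),
with an 8-neighbour within-slice mode for 2D fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedROI

__all__ = ["SizeZoneMatrix", "build_glszm", "glszm_features", "GLSZM_FEATURE_NAMES"]

def _slicewise_8() -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1] = True  # 8-connectivity within each slice, no cross-slice links
    return s


_STRUCTURES = {
    "3D-26": np.ones((3, 3, 3), dtype=bool),
    "2D-8": _slicewise_8(),
}

GLSZM_FEATURE_NAMES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]


@dataclass
class SizeZoneMatrix:
    """Zone counts P[i-1, j-1] for gray level i in 1..Ng, zone size j in 1..Jmax.

    Invariants: sum(P) == Nz (zone count) and sum over (i,j) of j*P == Nv
    (masked voxel count).
    """

    P: np.ndarray
    n_zones: int
    n_voxels: int

    @property
    def n_levels(self) -> int:
        return self.P.shape[0]


def build_glszm(roi: DiscretizedROI, connectivity: str = "3D-26") -> SizeZoneMatrix:
    """Build the size-zone matrix of a discretized ROI.

    Zones are connected components of equal-level masked voxels under the
    chosen connectivity ("3D-26" or "2D-8").
    """
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(
            f"unknown connectivity {connectivity!r}; expected one of "
            f"{sorted(_STRUCTURES)}"
        ) from None
    levels = roi.levels
    nv = int(roi.mask.sum())
    if nv == 0:
        raise ValueError("empty ROI")
    ng = roi.n_levels
    present = np.unique(levels[roi.mask])
    zones: list[tuple[int, int]] = []  # (level, size)
    for lv in present:
        lab, n = ndimage.label(levels == lv, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(lv), int(s)) for s in sizes)
    jmax = max(s for _, s in zones)
    P = np.zeros((ng, jmax), dtype=np.int64)
    for lv, s in zones:
        P[lv - 1, s - 1] += 1
    return SizeZoneMatrix(P=P, n_zones=len(zones), n_voxels=nv)


def glszm_features(szm: SizeZoneMatrix) -> dict[str, float]:
    """The 16 standard GLSZM features of a size-zone matrix."""
    if szm.n_zones < 1:
        raise ValueError("undefined GLSZM features: zero zones")
    P = szm.P.astype(np.float64)
    nz = float(szm.n_zones)
    nv = float(szm.n_voxels)
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per zone size
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    pnz = p[p > 0]
    return {
        "SmallAreaEmphasis": float((P / j**2).sum() / nz),
        "LargeAreaEmphasis": float((P * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "ZonePercentage": nz / nv,
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nz),
    }
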