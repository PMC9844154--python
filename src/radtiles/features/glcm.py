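"""Gray-level co-occurrence matrix (GLCM) texture features.

Co-occurrences are counted between masked voxel pairs at Chebyshev distance 1
along the 13 unique 3D directions, symmetrized and normalized per direction;
each of the 24 features is computed per direction and averaged (directions
with no valid pair are skipped).
"""

from __future__ import annotations

import numpy as np

from .preprocess import DiscretizedROI

__all__ = ["glcm_features", "GLCM_FEATURE_NAMES", "UNIQUE_OFFSETS_3D"]

#: Canonical half of the 26 distance-1 neighbour offsets (z, y, x).
UNIQUE_OFFSETS_3D: list[tuple[int, int, int]] = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
assert len(UNIQUE_OFFSETS_3D) == 13

GLCM_FEATURE_NAMES = [
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
]

_EPS = np.finfo(np.float64).eps


def _cooccurrence(levels: np.ndarray, mask: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset; both voxels masked."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, levels.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    ai, bi = a[valid] - 1, b[valid] - 1
    C = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(C, (ai, bi), 1.0)
    return C + C.T


def _direction_features(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii = i[:, None]
    jj = i[None, :]
    px = p.sum(axis=1)
    mu = float((i * px).sum())  # == mu_x == mu_y (symmetric p)
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    idx_sum = (ii + jj).astype(int) - 2
    idx_diff = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, idx_sum.ravel(), p.ravel())
    np.add.at(p_diff, idx_diff.ravel(), p.ravel())

    pnz = p[p > 0]
    hxy = float(-(pnz * np.log2(pnz)).sum())
    px_nz = px[px > 0]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    pxy_outer = px[:, None] * px[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_outer = np.where(pxy_outer > 0, np.log2(pxy_outer + _EPS), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(pxy_outer * log_outer).sum())

    da = float((k_diff * p_diff).sum())
    pd_nz = p_diff[p_diff > 0]
    ps_nz = p_sum[p_sum > 0]

    corr = 1.0 if sigma2 == 0 else float(((ii * jj * p).sum() - mu * mu) / sigma2)
    imc1 = 0.0 if hx == 0 else (hxy - hxy1) / hx
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
    keep = px > 0
    if keep.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        Q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2].real)))

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(pd_nz * np.log2(pd_nz)).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p_diff / (1 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1 + (k_diff / ng) ** 2)).sum()),
        "Id": float((p_diff / (1 + k_diff)).sum()),
        "Idn": float((p_diff / (1 + k_diff / ng)).sum()),
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(ps_nz * np.log2(ps_nz)).sum()),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def glcm_features(
    roi: DiscretizedROI,
    offsets: list[tuple[int, int, int]] | None = None,
) -> dict[str, float]:
    """The 24 GLCM features, averaged over distance-1 directions.

    ``offsets`` restricts the directions (used by 1D/2D fixtures); default is
    the 13 unique 3D neighbour directions.

    Raises
    ------
    ValueError
        If no masked voxel pair co-occurs in any direction (e.g. a
        single-voxel ROI).
    """
    offsets = UNIQUE_OFFSETS_3D if offsets is None else offsets
    ng = int(roi.masked_levels.max())  # trailing empty levels carry no mass
    per_direction = []
    for off in offsets:
        C = _cooccurrence(roi.levels, roi.mask, ng, off)
        total = C.sum()
        if total == 0:
            continue
        per_direction.append(_direction_features(C / total, ng))
    if not per_direction:
        raise ValueError("undefined GLCM features: no co-occurring voxel pairs")
    return {
        name: float(np.mean([d[name] for d in per_direction]))
        for name in GLCM_FEATURE_NAMES
    }
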