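"""Full 88-feature extraction over one masked CT volume.

The catalogue has seven categories — first-order (18), shape (14), GLCM (24),
GLSZM (16), CDF (5), physical (2), fractal (9) — extracted after isotropic
resampling and gray-level discretization.  Feature names are prefixed with
their category (e.g. ``glszm_GrayLevelVariance``); a machine-readable
manifest of the catalogue ships with the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .firstorder import FIRST_ORDER_FEATURE_NAMES, first_order_features
from .glcm import GLCM_FEATURE_NAMES, glcm_features
from .glszm import GLSZM_FEATURE_NAMES, build_glszm, glszm_features
from .preprocess import ROIMask, VoxelVolume, discretize, resample_isotropic
from .reconstructed import (
    CDF_FEATURE_NAMES,
    FRACTAL_FEATURE_NAMES,
    PHYSICAL_FEATURE_NAMES,
    cdf_features,
    fractal_features,
    physical_features,
)
from .shape import SHAPE_FEATURE_NAMES, shape_features

__all__ = [
    "ExtractionConfig",
    "FeatureVector",
    "extract_features",
    "feature_catalogue",
    "CATEGORY_COUNTS",
]

CATEGORY_COUNTS = {
    "first_order": 18,
    "shape": 14,
    "glcm": 24,
    "glszm": 16,
    "cdf": 5,
    "physical": 2,
    "fractal": 9,
}

CATEGORY_FEATURES: dict[str, list[str]] = {
    "first_order": FIRST_ORDER_FEATURE_NAMES,
    "shape": SHAPE_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "cdf": CDF_FEATURE_NAMES,
    "physical": PHYSICAL_FEATURE_NAMES,
    "fractal": FRACTAL_FEATURE_NAMES,
}

#: Families whose definitions are in-package reconstructions rather than the
#: community-standard catalogue.
RECONSTRUCTED_CATEGORIES = ("cdf", "physical", "fractal")


@dataclass
class ExtractionConfig:
    """Every tunable that affects feature values."""

    target_spacing_mm: float = 1.0
    resample: bool = True
    bin_count: int | None = 32
    bin_width: float | None = None
    connectivity: str = "3D-26"
    categories: tuple[str, ...] | None = None  # None = all seven

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["provenance"] = {c: "reconstructed" for c in RECONSTRUCTED_CATEGORIES}
        return d


@dataclass
class FeatureVector:
    """Named values of the 88 features of one ROI."""

    values: dict[str, float]
    categories: dict[str, str]
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cat in self.categories.values():
            counts[cat] = counts.get(cat, 0) + 1
        return counts


def feature_catalogue() -> pd.DataFrame:
    """The 88-feature catalogue as a (name, category, provenance) table."""
    rows = [
        {
            "name": f"{cat}_{feat}",
            "category": cat,
            "provenance": "reconstructed" if cat in RECONSTRUCTED_CATEGORIES else "standard",
        }
        for cat, names in CATEGORY_FEATURES.items()
        for feat in names
    ]
    return pd.DataFrame(rows)


def feature_names() -> list[str]:
    return list(feature_catalogue()["name"])


def extract_features(
    volume: VoxelVolume,
    mask: ROIMask,
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Extract the radiomic features of a masked volume.

    Pipeline: optional isotropic resampling -> discretization -> per-category
    extraction.  With the default config all 88 features are produced;
    ``config.categories`` restricts to a subset (e.g. for fixtures too small
    for the box-counting family).  Any category failure re-raises with the
    category named.
    """
    config = config or ExtractionConfig()
    if volume.shape != mask.mask.shape:
        raise ValueError("volume and mask shapes differ")
    if config.resample:
        volume, mask = resample_isotropic(volume, mask, config.target_spacing_mm)
    roi = discretize(volume, mask, bin_count=config.bin_count, bin_width=config.bin_width)

    extractors = {
        "first_order": lambda: first_order_features(volume, mask, roi),
        "shape": lambda: shape_features(mask, volume.spacing_mm),
        "glcm": lambda: glcm_features(roi),
        "glszm": lambda: glszm_features(build_glszm(roi, config.connectivity)),
        "cdf": lambda: cdf_features(volume, mask),
        "physical": lambda: physical_features(volume, mask),
        "fractal": lambda: fractal_features(volume, mask),
    }
    wanted = extractors if config.categories is None else {
        c: extractors[c] for c in config.categories
    }
    values: dict[str, float] = {}
    categories: dict[str, str] = {}
    for cat, fn in wanted.items():
        try:
            feats = fn()
        except Exception as exc:
            raise type(exc)(f"{cat} extraction failed: {exc}") from exc
        if list(feats) != CATEGORY_FEATURES[cat]:
            raise RuntimeError(f"{cat}: catalogue mismatch")
        for name, val in feats.items():
            values[f"{cat}_{name}"] = float(val)
            categories[f"{cat}_{name}"] = cat
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    manifest = config.to_manifest()
    manifest["binning_realized"] = roi.binning
    return FeatureVector(values=values, categories=categories, manifest=manifest)


def extract_cohort(
    pairs,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Extract features for (sample_id, volume, mask) triples into a table."""
    rows = {}
    for sample_id, volume, mask in pairs:
        rows[sample_id] = extract_features(volume, mask, config).values
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df
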