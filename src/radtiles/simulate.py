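"""Synthetic paired imaging / pathology / outcome cohorts.

A single latent heterogeneity score h in [0, 1] per subject drives the whole
effect chain the downstream modules are meant to detect:

* imaging — voxel texture variance grows with h, and contiguous
  low-attenuation (necrotic) blobs occupy a volume fraction growing with
  (1 - h), so size-zone statistics of the volume track h;
* pathology — each 1 mm^2 grid is TIL-enriched (inflamed or immune-excluded)
  with probability logistic(a + til_effect * h);
* outcome — event times are exponential with hazard
  baseline_hazard * exp(log_hazard_per_tiles * TILes), with independent
  exponential censoring.

Everything is reproducible from one global seed, expanded into per-subject
substreams through numpy's SeedSequence spawning-key mechanism so subjects
are independent and insertion-order invariant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .features import feature_names
from .features.preprocess import ROIMask, VoxelVolume
from .tiles import (
    DEFAULT_INTRATUMORAL_THRESHOLD,
    DEFAULT_STROMAL_THRESHOLD,
    GridCell,
    GridTILMap,
    tiles_score,
)

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "CohortBundle",
    "simulate_tumor_volume",
    "simulate_til_grid",
    "simulate_outcomes",
    "simulate_cohort",
    "simulate_feature_matrix",
]

#: Names of the two causal columns in synthetic feature matrices.
CAUSAL_VARIANCE_FEATURE = "glszm_GrayLevelVariance"
CAUSAL_LARGE_AREA_FEATURE = "glszm_LargeAreaLowGrayLevelEmphasis"

#: Gray-level bin width (HU) for texture->TILes effect-chain checks.
#: Fixed-bin-count discretization rescales every ROI to its own intensity
#: range and so normalizes away the absolute texture variance the generator
#: modulates; the calibrated HU scale makes fixed-width binning the right
#: lens for that effect.
EFFECT_CHAIN_BIN_WIDTH_HU = 25.0


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the scale of the clinical setting being emulated:
    220 subjects (the training-cohort size), tumors of a few cm at 1 mm
    isotropic voxels, PFS-scale hazards (median a few months), and a
    protective TILes effect on the hazard.
    """

    n_subjects: int = 220
    volume_shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    heterogeneity_range: tuple[float, float] = (0.0, 1.0)
    texture_sigma0: float = 15.0  # HU noise std at h = 0
    texture_effect: float = 35.0  # extra HU noise std at h = 1
    necrosis_effect: float = 0.25  # necrotic volume fraction at h = 0
    necrosis_drop_hu: float = 20.0  # plateau below the base attenuation
    smoothing_width: float = 2.0  # Gaussian-field kernel width, voxels
    base_hu: float = 40.0
    background_hu: float = -800.0
    til_intercept: float = -1.0  # logit P(grid enriched) at h = 0
    til_effect: float = 3.0  # slope of the logit in h
    grids_per_sample: int = 20
    baseline_hazard: float = 0.25  # events per month at TILes = 0
    log_hazard_per_tiles: float = -1.5
    censoring_rate: float = 0.03  # censorings per month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.grids_per_sample < 1:
            raise ValueError("counts must be strictly positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        lo, hi = self.heterogeneity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("heterogeneity_range must be within [0, 1]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")


@dataclass
class SubjectRecord:
    """One subject of a synthetic cohort."""

    subject_id: str
    latent_h: float
    volume: VoxelVolume | None
    mask: ROIMask | None
    til_map: GridTILMap
    true_tiles: float  # generating probability, not the realized score
    realized_tiles: float
    time_months: float
    event: int


@dataclass
class CohortBundle:
    subjects: list[SubjectRecord]
    config: SimulationConfig

    def outcome_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "latent_h": [s.latent_h for s in self.subjects],
                "true_tiles": [s.true_tiles for s in self.subjects],
                "realized_tiles": [s.realized_tiles for s in self.subjects],
                "time_months": [s.time_months for s in self.subjects],
                "event": [s.event for s in self.subjects],
            }
        )


def _subject_rng(seed: int, subject: int, stream: int) -> np.random.Generator:
    # counter-based substreams: independent of insertion order
    return np.random.default_rng(np.random.SeedSequence([seed, subject, stream]))


def simulate_tumor_volume(
    h: float, cfg: SimulationConfig, seed: int
) -> tuple[VoxelVolume, ROIMask]:
    """Simulate one CT-like tumor volume with its ellipsoidal ROI mask.

    Intensity = smooth base + Gaussian-field texture whose std is
    texture_sigma0 + texture_effect * h, plus spherical low-attenuation
    blobs filling a volume fraction of about necrosis_effect * (1 - h).
    """
    lo, hi = cfg.heterogeneity_range
    if not (lo <= h <= hi):
        raise ValueError(f"h={h} outside heterogeneity_range {cfg.heterogeneity_range}")
    shape = tuple(int(n) for n in cfg.volume_shape)
    if min(shape) < 12:
        raise ValueError(f"volume {shape} too small for the minimal ROI (need >= 12 per axis)")
    rng = np.random.default_rng(seed)

    center = np.array(shape) / 2.0
    semi = np.array([rng.uniform(0.28, 0.40) * n for n in shape])
    zz, yy, xx = np.indices(shape)
    dist2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    mask = dist2 <= 1.0

    white = rng.normal(size=shape)
    field_ = ndimage.gaussian_filter(white, cfg.smoothing_width)
    field_ /= field_.std()
    sigma = cfg.texture_sigma0 + cfg.texture_effect * h
    intensities = np.full(shape, cfg.background_hu)
    intensities[mask] = cfg.base_hu + sigma * field_[mask]

    frac_target = cfg.necrosis_effect * (1.0 - h)
    if frac_target > 0:
        n_mask = int(mask.sum())
        placed = np.zeros(shape, dtype=bool)
        budget = frac_target * n_mask
        centers = np.argwhere(mask)
        for _ in range(64):  # blob insertion until the volume budget is met
            if placed.sum() >= budget:
                break
            c = centers[rng.integers(len(centers))]
            r = rng.uniform(1.5, max(2.0, 0.18 * min(shape)))
            blob = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
            placed |= blob & mask
        if placed.any():
            intensities[placed] = (
                cfg.base_hu
                - cfg.necrosis_drop_hu
                + rng.normal(0.0, 3.0, size=int(placed.sum()))
            )

    return VoxelVolume(intensities, cfg.spacing_mm), ROIMask(mask)


def simulate_til_grid(h: float, cfg: SimulationConfig, seed: int) -> GridTILMap:
    """Simulate the gridded TIL map of one sample.

    Each grid is enriched with probability logistic(til_intercept +
    til_effect * h); enriched grids split evenly between inflamed and
    immune-excluded density patterns.
    """
    rng = np.random.default_rng(seed)
    p = float(expit(cfg.til_intercept + cfg.til_effect * h))
    cells = []
    for g in range(cfg.grids_per_sample):
        enriched = rng.random() < p
        inflamed = enriched and rng.random() < 0.5
        if inflamed:
            intra = rng.uniform(DEFAULT_INTRATUMORAL_THRESHOLD, 1500.0)
            stromal = rng.uniform(0.0, DEFAULT_STROMAL_THRESHOLD)
        elif enriched:
            intra = rng.uniform(0.0, DEFAULT_INTRATUMORAL_THRESHOLD)
            stromal = rng.uniform(DEFAULT_STROMAL_THRESHOLD, 2000.0)
        else:
            intra = rng.uniform(0.0, DEFAULT_INTRATUMORAL_THRESHOLD)
            stromal = rng.uniform(0.0, DEFAULT_STROMAL_THRESHOLD)
        cells.append(
            GridCell(
                grid_id=f"g{g:03d}",
                intratumoral_til_density=float(intra),
                stromal_til_density=float(stromal),
                epithelium_area=float(rng.uniform(0.05, 0.3)),
                tme_area=float(rng.uniform(0.5, 1.0)),
            )
        )
    return GridTILMap(sample_id=f"seed{seed}", cells=cells)


def simulate_outcomes(tiles: float, cfg: SimulationConfig, seed: int) -> tuple[float, int]:
    """Draw one (observed time in months, event flag) pair.

    Event time is exponential with hazard baseline_hazard *
    exp(log_hazard_per_tiles * tiles); censoring is an independent
    exponential with rate censoring_rate (never censors when the rate is 0).
    """
    if not (0.0 <= tiles <= 1.0):
        raise ValueError("tiles must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hazard_per_tiles * tiles)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_rate) if cfg.censoring_rate > 0 else np.inf
    if t_event <= t_cens:
        return float(t_event), 1
    return float(t_cens), 0


def simulate_cohort(cfg: SimulationConfig, with_volumes: bool = True) -> CohortBundle:
    """Generate the full paired cohort under one global seed."""
    subjects = []
    for i in range(cfg.n_subjects):
        h_rng = _subject_rng(cfg.seed, i, 0)
        lo, hi = cfg.heterogeneity_range
        h = float(h_rng.uniform(lo, hi))
        vol, mask = (None, None)
        if with_volumes:
            vol_seed = _subject_rng(cfg.seed, i, 1).integers(2**31)
            vol, mask = simulate_tumor_volume(h, cfg, int(vol_seed))
        grid_seed = int(_subject_rng(cfg.seed, i, 2).integers(2**31))
        til_map = simulate_til_grid(h, cfg, grid_seed)
        til_map.sample_id = f"s{i:04d}"
        true_tiles = float(expit(cfg.til_intercept + cfg.til_effect * h))
        realized = tiles_score(til_map, min_grids=min(10, cfg.grids_per_sample))
        out_seed = int(_subject_rng(cfg.seed, i, 3).integers(2**31))
        time_m, event = simulate_outcomes(true_tiles, cfg, out_seed)
        subjects.append(
            SubjectRecord(
                subject_id=f"s{i:04d}",
                latent_h=h,
                volume=vol,
                mask=mask,
                til_map=til_map,
                true_tiles=true_tiles,
                realized_tiles=realized.tiles if realized.tiles is not None else np.nan,
                time_months=time_m,
                event=event,
            )
        )
    return CohortBundle(subjects=subjects, config=cfg)


def simulate_feature_matrix(
    n_subjects: int = 220,
    seed: int = 0,
    variance_slope: float = 300.0,
    large_area_slope: float = -30000.0,
    noise_sd_fraction: float = 0.25,
    response_noise_sd: float = 0.04,
    til_intercept: float = -1.0,
    til_effect: float = 3.0,
) -> pd.DataFrame:
    """A synthetic 88-feature cohort matrix with two causal texture columns.

    The latent heterogeneity h drives the response (expected TILes =
    logistic(til_intercept + til_effect*h) plus Gaussian noise, clipped to
    [0, 1]) and the two causal columns: the GLSZM gray-level-variance
    feature rises with h, the large-area-low-gray feature falls with h,
    at the attenuation-texture scales typical of each (1e2-1e3 vs 1e4-1e5).
    The 86 remaining catalogue features are h-independent noise at assorted
    scales.  Returns a DataFrame with a ``tiles`` response column.
    """
    rng = np.random.default_rng(seed)
    names = feature_names()
    h = rng.uniform(0.0, 1.0, n_subjects)
    tiles = expit(til_intercept + til_effect * h) + rng.normal(0, response_noise_sd, n_subjects)
    tiles = np.clip(tiles, 0.0, 1.0)

    X = pd.DataFrame(index=pd.Index([f"s{i:04d}" for i in range(n_subjects)], name="sample_id"))
    scales = 10.0 ** rng.uniform(-1, 4, len(names))
    for name, scale in zip(names, scales):
        if name == CAUSAL_VARIANCE_FEATURE:
            base, slope = 400.0, variance_slope
            col = base + slope * h + rng.normal(0, abs(slope) * noise_sd_fraction, n_subjects)
        elif name == CAUSAL_LARGE_AREA_FEATURE:
            base, slope = 60000.0, large_area_slope
            col = base + slope * h + rng.normal(0, abs(slope) * noise_sd_fraction, n_subjects)
        else:
            col = scale * (1.0 + 0.3 * rng.normal(size=n_subjects))
        X[name] = col
    X["tiles"] = tiles
    return X


def write_cohort(bundle: CohortBundle, out_dir, image_format: str = "nii.gz") -> None:
    """Write a cohort to disk: volumes/masks, grid CSV, outcome CSV, manifest."""
    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .tiles import write_grid_maps_csv

    write_grid_maps_csv([s.til_map for s in bundle.subjects], out / "til_grids.csv")
    bundle.outcome_frame().to_csv(out / "outcomes.csv", index=False)
    manifest = {
        "config": asdict(bundle.config),
        "true_parameters": {
            s.subject_id: {"latent_h": s.latent_h, "true_tiles": s.true_tiles}
            for s in bundle.subjects
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    img_dir = out / "images"
    for s in bundle.subjects:
        if s.volume is None:
            continue
        img_dir.mkdir(exist_ok=True)
        rio.write_volume(s.volume, img_dir / f"{s.subject_id}_image.{image_format}")
        rio.write_mask(s.mask, s.volume, img_dir / f"{s.subject_id}_mask.{image_format}")
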