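"""TIL-enrichment scoring of gridded pathology maps.

A whole-slide H&E image is evaluated on 1 mm^2 grids.  Each grid carries an
intra-tumoral and a stromal TIL density (cells/mm^2), the cancer-epithelium
area it contains, and its analyzable tumor-microenvironment (TME) area.
Grids are classified into immune phenotypes (inflamed / immune-excluded /
desert), and the TIL enrichment score (TILes) of a sample is the fraction of
analyzable TME area occupied by inflamed or immune-excluded grids.

The density thresholds that define "high" TIL density are inputs: in the
clinical workflow they live inside the upstream AI pathology model, which is
out of scope here.  The defaults below are the synthetic-cohort conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "GridCell",
    "GridTILMap",
    "TILesResult",
    "classify_grid",
    "qc_sample",
    "tiles_score",
    "read_grid_maps_csv",
    "write_grid_maps_csv",
    "DEFAULT_INTRATUMORAL_THRESHOLD",
    "DEFAULT_STROMAL_THRESHOLD",
]

Phenotype = Literal["inflamed", "immune-excluded", "desert", "non-evaluable"]

#: Synthetic-cohort defaults for "high" TIL density (cells per mm^2).
DEFAULT_INTRATUMORAL_THRESHOLD = 300.0
DEFAULT_STROMAL_THRESHOLD = 600.0

GRID_CSV_COLUMNS = [
    "sample_id",
    "grid_id",
    "intratumoral_til_density",
    "stromal_til_density",
    "epithelium_area",
    "tme_area",
]


@dataclass(frozen=True)
class GridCell:
    """One 1 mm^2 evaluation grid of a pathology slide."""

    grid_id: str
    intratumoral_til_density: float
    stromal_til_density: float
    epithelium_area: float
    tme_area: float

    def __post_init__(self) -> None:
        if self.intratumoral_til_density < 0 or self.stromal_til_density < 0:
            raise ValueError(f"grid {self.grid_id}: TIL densities must be >= 0")
        if self.epithelium_area < 0 or self.tme_area < 0:
            raise ValueError(f"grid {self.grid_id}: areas must be >= 0")


@dataclass
class GridTILMap:
    """All evaluation grids of one sample."""

    sample_id: str
    cells: list[GridCell] = field(default_factory=list)
    grid_area: float = 1.0

    def __post_init__(self) -> None:
        ids = [c.grid_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError(f"sample {self.sample_id}: duplicate grid_ids")

    @property
    def total_epithelium_area(self) -> float:
        return float(sum(c.epithelium_area for c in self.cells))


@dataclass
class TILesResult:
    """TILes score of one sample, with its QC verdict.

    ``tiles`` is None when QC fails or the score is undefined
    (zero evaluable TME area).
    """

    sample_id: str
    tiles: float | None
    n_grids_evaluable: int
    qc_pass: bool
    qc_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "tiles": self.tiles,
            "n_grids_evaluable": self.n_grids_evaluable,
            "qc_pass": self.qc_pass,
            "qc_reason": self.qc_reason,
        }


def classify_grid(
    cell: GridCell,
    intratumoral_threshold: float = DEFAULT_INTRATUMORAL_THRESHOLD,
    stromal_threshold: float = DEFAULT_STROMAL_THRESHOLD,
) -> Phenotype:
    """Assign the immune phenotype of one grid.

    A grid with no analyzable TME area is non-evaluable.  Otherwise it is
    inflamed when intra-tumoral TIL density reaches ``intratumoral_threshold``
    (inclusive), immune-excluded when stromal density reaches
    ``stromal_threshold``, and desert when neither does.  When both densities
    reach their thresholds the grid is inflamed: intra-tumoral infiltration
    subsumes stromal infiltration (a fixed convention).
    """
    if intratumoral_threshold <= 0 or stromal_threshold <= 0:
        raise ValueError("classification thresholds must be > 0")
    if cell.tme_area == 0:
        return "non-evaluable"
    if cell.intratumoral_til_density >= intratumoral_threshold:
        return "inflamed"
    if cell.stromal_til_density >= stromal_threshold:
        return "immune-excluded"
    return "desert"


def qc_sample(
    map_: GridTILMap,
    min_epithelium_mm2: float = 0.5,
    min_grids: int = 10,
) -> tuple[bool, str]:
    """Sample-level quality control.

    A sample fails when its whole-slide cancer-epithelium area is less than
    ``min_epithelium_mm2`` or when fewer than ``min_grids`` grids are
    evaluable.  Both bounds are strict: a sample with exactly 0.5 mm^2 of
    epithelium and exactly 10 evaluable grids passes.
    """
    n_evaluable = sum(1 for c in map_.cells if c.tme_area > 0)
    reasons = []
    if map_.total_epithelium_area < min_epithelium_mm2:
        reasons.append(
            f"less than {min_epithelium_mm2} mm^2 cancer epithelium "
            f"({map_.total_epithelium_area:g} mm^2)"
        )
    if n_evaluable < min_grids:
        reasons.append(f"fewer than {min_grids} grids ({n_evaluable} evaluable)")
    return (not reasons, "; ".join(reasons))


def tiles_score(
    map_: GridTILMap,
    intratumoral_threshold: float = DEFAULT_INTRATUMORAL_THRESHOLD,
    stromal_threshold: float = DEFAULT_STROMAL_THRESHOLD,
    min_epithelium_mm2: float = 0.5,
    min_grids: int = 10,
    area_weighted: bool = True,
    skip_qc: bool = False,
) -> TILesResult:
    """Compute the TIL enrichment score of one sample.

    TILes = (TME area of grids classified inflamed or immune-excluded)
            / (TME area of all evaluable grids), in [0, 1].

    The division is by analyzable TME area, so grids are area-weighted by
    default; ``area_weighted=False`` switches to a plain grid-count fraction.
    QC runs first unless ``skip_qc``; a failing sample gets ``tiles=None``.
    """
    qc_pass, qc_reason = qc_sample(map_, min_epithelium_mm2, min_grids)
    evaluable = [c for c in map_.cells if c.tme_area > 0]
    if not skip_qc and not qc_pass:
        return TILesResult(map_.sample_id, None, len(evaluable), False, qc_reason)

    total = sum(c.tme_area for c in evaluable) if area_weighted else len(evaluable)
    if total == 0:
        return TILesResult(
            map_.sample_id, None, 0, qc_pass, qc_reason or "zero analyzable TME area"
        )
    enriched = 0.0
    for c in evaluable:
        phen = classify_grid(c, intratumoral_threshold, stromal_threshold)
        if phen in ("inflamed", "immune-excluded"):
            enriched += c.tme_area if area_weighted else 1
    return TILesResult(
        map_.sample_id, enriched / total, len(evaluable), qc_pass, qc_reason
    )


def read_grid_maps_csv(path) -> list[GridTILMap]:
    """Read grid maps from CSV (one row per grid; see GRID_CSV_COLUMNS)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "grid_id": str})
    missing = [c for c in GRID_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid-map CSV missing columns: {missing}")
    maps = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        cells = [
            GridCell(
                grid_id=str(r.grid_id),
                intratumoral_til_density=float(r.intratumoral_til_density),
                stromal_til_density=float(r.stromal_til_density),
                epithelium_area=float(r.epithelium_area),
                tme_area=float(r.tme_area),
            )
            for r in grp.itertuples()
        ]
        maps.append(GridTILMap(sample_id=str(sample_id), cells=cells))
    return maps


def write_grid_maps_csv(maps: Iterable[GridTILMap], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "grid_id": c.grid_id,
            "intratumoral_til_density": c.intratumoral_til_density,
            "stromal_til_density": c.stromal_til_density,
            "epithelium_area": c.epithelium_area,
            "tme_area": c.tme_area,
        }
        for m in maps
        for c in m.cells
    ]
    pd.DataFrame(rows, columns=GRID_CSV_COLUMNS).to_csv(path, index=False)
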