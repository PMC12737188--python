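"""Detection of high-RI aggregates and per-cell uptake metrics.

Aggregates are connected components of the strict high-RI mask (RI > 1.36
by default; the boundary value is excluded).  Each component is assigned to
the cell containing its centroid; components outside every cell keep
``cell_id = 0`` and are always reported, so voxel accounting closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DataError
from .segmentation import CellInstance, connectivity_structure
from .volume_io import RITomogram, VoxelSpacing

__all__ = [
    "AggregateParams",
    "AggregateRecord",
    "CellStats",
    "high_ri_mask",
    "detect_aggregates",
    "compute_cell_stats",
    "aggregate_size_distribution",
]


@dataclass
class AggregateParams:
    high_ri_threshold: float = 1.36
    min_aggregate_voxels: int = 2
    connectivity: int = 26
    restrict_to_cells: bool = True

    def __post_init__(self) -> None:
        if not 1.0 < self.high_ri_threshold < 2.0:
            raise ConfigError(
                f"high-RI threshold {self.high_ri_threshold} not in (1, 2)"
            )
        if self.min_aggregate_voxels < 1:
            raise ConfigError("min_aggregate_voxels must be >= 1")
        connectivity_structure(self.connectivity)


@dataclass
class AggregateRecord:
    id: int
    cell_id: int
    voxel_count: int
    volume_um3: float
    mean_ri: float
    max_ri: float
    centroid: tuple[float, float, float]


@dataclass
class CellStats:
    """Per-cell uptake summary; ``mean_aggregate_volume_um3`` is NaN when the
    cell holds no aggregates (missing, not zero)."""

    cell_id: int
    cell_volume_um3: float
    mean_cell_ri: float
    aggregate_count: int
    total_np_volume_um3: float
    np_volume_fraction: float
    mean_aggregate_volume_um3: float


def high_ri_mask(tomogram: RITomogram, params: AggregateParams) -> np.ndarray:
    """Binary mask of voxels with RI strictly above the high-RI threshold."""
    return tomogram.grid > params.high_ri_threshold


def detect_aggregates(
    tomogram: RITomogram,
    cell_labels: np.ndarray | None,
    params: AggregateParams,
    spacing: VoxelSpacing,
) -> list[AggregateRecord]:
    """Connected high-RI components as aggregate records.

    Components smaller than ``min_aggregate_voxels`` are dropped.  Survivors
    are renumbered 1..K by descending voxel count (ties by original label).
    """
    mask = high_ri_mask(tomogram, params)
    structure = connectivity_structure(params.connectivity)
    labels, n_raw = ndimage.label(mask, structure=structure)
    if n_raw == 0:
        return []
    counts = np.bincount(labels.ravel(), minlength=n_raw + 1)
    keep = [
        lab for lab in range(1, n_raw + 1) if counts[lab] >= params.min_aggregate_voxels
    ]
    keep.sort(key=lambda lab: (-counts[lab], lab))

    flat = labels.ravel()
    ri_flat = tomogram.grid.ravel()
    sums = np.bincount(flat, weights=ri_flat, minlength=n_raw + 1)
    maxs = ndimage.maximum(tomogram.grid, labels=labels, index=np.arange(1, n_raw + 1))
    zz, yy, xx = np.nonzero(labels)
    lab_nz = labels[zz, yy, xx]
    cz = np.bincount(lab_nz, weights=zz, minlength=n_raw + 1)
    cy = np.bincount(lab_nz, weights=yy, minlength=n_raw + 1)
    cx = np.bincount(lab_nz, weights=xx, minlength=n_raw + 1)

    vv = spacing.voxel_volume
    shape = tomogram.grid.shape
    records: list[AggregateRecord] = []
    for new_id, lab in enumerate(keep, start=1):
        n = int(counts[lab])
        max_ri = float(maxs[lab - 1])
        # summation rounding can push the mean a ulp past the max
        mean_ri = min(float(sums[lab] / n), max_ri)
        centroid = (cz[lab] / n, cy[lab] / n, cx[lab] / n)
        if cell_labels is not None:
            idx = tuple(
                int(np.clip(round(c), 0, s - 1)) for c, s in zip(centroid, shape)
            )
            cell_id = int(cell_labels[idx])
        else:
            cell_id = 0
        records.append(
            AggregateRecord(
                id=new_id,
                cell_id=cell_id,
                voxel_count=n,
                volume_um3=n * vv,
                mean_ri=mean_ri,
                max_ri=max_ri,
                centroid=tuple(float(c) for c in centroid),
            )
        )
    return records


def compute_cell_stats(
    cells: list[CellInstance],
    aggregates: list[AggregateRecord],
    spacing: VoxelSpacing,
) -> list[CellStats]:
    """Join aggregates onto their parent cells.

    Aggregates with ``cell_id = 0`` (outside all cells) are ignored here;
    an aggregate referencing an unknown nonzero cell id is an error.
    """
    by_cell: dict[int, list[AggregateRecord]] = {c.id: [] for c in cells}
    for agg in aggregates:
        if agg.cell_id == 0:
            continue
        if agg.cell_id not in by_cell:
            raise DataError(
                f"aggregate {agg.id} references unknown cell id {agg.cell_id}"
            )
        by_cell[agg.cell_id].append(agg)

    out: list[CellStats] = []
    for cell in cells:
        members = by_cell[cell.id]
        total = sum(a.volume_um3 for a in members)
        count = len(members)
        out.append(
            CellStats(
                cell_id=cell.id,
                cell_volume_um3=cell.volume_um3,
                mean_cell_ri=cell.mean_ri,
                aggregate_count=count,
                total_np_volume_um3=total,
                np_volume_fraction=100.0 * total / cell.volume_um3,
                mean_aggregate_volume_um3=(total / count) if count else math.nan,
            )
        )
    return out


def aggregate_size_distribution(
    aggregates,
    cutoff_um3: float = 1.0,
    bin_width_um3: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Size histogram, cumulative frequency and % of aggregates below cutoff.

    *aggregates* may be AggregateRecord objects or raw volumes (µm³).
    The cumulative table is monotone nondecreasing and ends at 100%.
    """
    vols = np.asarray(
        [a.volume_um3 if isinstance(a, AggregateRecord) else float(a) for a in aggregates],
        dtype=float,
    )
    if vols.size == 0:
        raise DataError("aggregate size distribution needs at least one aggregate")
    if bin_width_um3 <= 0 or cutoff_um3 <= 0:
        raise ConfigError("cutoff and bin width must be > 0")
    n_bins = int(np.ceil(vols.max() / bin_width_um3)) or 1
    idx = np.minimum(
        np.floor(vols / bin_width_um3).astype(np.int64), n_bins - 1
    )
    counts = np.bincount(idx, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width_um3
    hist = pd.DataFrame({"bin_center_um3": centers, "count": counts})
    cum = pd.DataFrame(
        {
            "bin_upper_um3": (np.arange(n_bins) + 1) * bin_width_um3,
            "cumulative_pct": 100.0 * np.cumsum(counts) / vols.size,
        }
    )
    fraction_below = 100.0 * float(np.count_nonzero(vols < cutoff_um3)) / vols.size
    return hist, cum, fraction_below
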