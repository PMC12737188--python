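"""Cell delineation from RI tomograms.

A voxel belongs to the cellular foreground iff its RI is at or above the
background threshold (default 1.34; values below it are excluded, so the
boundary value itself is foreground).  Cell instances are connected
components of that mask; enclosed background (nuclei, low-RI inclusions) is
filled per component before statistics so reported volumes are whole-cell
volumes.  Touching cells are not split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DataError
from .volume_io import RITomogram, VoxelSpacing

__all__ = [
    "SegmentationParams",
    "CellInstance",
    "foreground_mask",
    "segment_cells",
    "ri_histogram",
    "mean_cell_ri",
    "connectivity_structure",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-neighbour adjacency."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except (KeyError, ValueError) as exc:
        raise ConfigError(
            f"connectivity must be one of 6, 18, 26; got {connectivity!r}"
        ) from exc
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class SegmentationParams:
    background_ri_threshold: float = 1.34
    min_cell_volume_um3: float = 200.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 1.0 < self.background_ri_threshold < 2.0:
            raise ConfigError(
                f"background threshold {self.background_ri_threshold} not in (1, 2)"
            )
        if self.min_cell_volume_um3 < 0:
            raise ConfigError("min_cell_volume_um3 must be >= 0")
        connectivity_structure(self.connectivity)


@dataclass
class CellInstance:
    """One segmented cell, hole-filled; volumes in µm³, centroid in voxels."""

    id: int
    voxel_count: int
    volume_um3: float
    mean_ri: float
    centroid: tuple[float, float, float]


def foreground_mask(tomogram: RITomogram, params: SegmentationParams) -> np.ndarray:
    """Binary cell/background mask: foreground iff RI >= threshold."""
    return tomogram.grid >= params.background_ri_threshold


def segment_cells(
    mask: np.ndarray,
    params: SegmentationParams,
    spacing: VoxelSpacing,
    tomogram: RITomogram | None = None,
) -> tuple[np.ndarray, list[CellInstance]]:
    """Label connected foreground components as cells.

    Components below ``min_cell_volume_um3`` are discarded.  Survivors are
    renumbered 1..K by descending voxel count (ties broken by original label
    order, so the result is deterministic) and hole-filled before stats.
    Returns the relabeled volume and per-cell records; an empty mask yields
    an empty list, not an error.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise DataError("mask must be 3D")
    structure = connectivity_structure(params.connectivity)
    raw_labels, n_raw = ndimage.label(mask, structure=structure)
    out = np.zeros_like(raw_labels, dtype=np.int32)
    if n_raw == 0:
        return out, []

    counts = np.bincount(raw_labels.ravel(), minlength=n_raw + 1)
    vv = spacing.voxel_volume
    keep = [
        lab
        for lab in range(1, n_raw + 1)
        if counts[lab] * vv >= params.min_cell_volume_um3
    ]
    keep.sort(key=lambda lab: (-counts[lab], lab))

    objects = ndimage.find_objects(raw_labels)
    cells: list[CellInstance] = []
    for new_id, lab in enumerate(keep, start=1):
        sl = objects[lab - 1]
        comp = raw_labels[sl] == lab
        filled = ndimage.binary_fill_holes(comp)
        out[sl][filled] = new_id
        nvox = int(filled.sum())
        zz, yy, xx = np.nonzero(filled)
        centroid = (
            float(zz.mean() + sl[0].start),
            float(yy.mean() + sl[1].start),
            float(xx.mean() + sl[2].start),
        )
        if tomogram is not None:
            mean_ri = float(tomogram.grid[sl][filled].mean())
        else:
            mean_ri = float("nan")
        cells.append(
            CellInstance(
                id=new_id,
                voxel_count=nvox,
                volume_um3=nvox * vv,
                mean_ri=mean_ri,
                centroid=centroid,
            )
        )
    return out, cells


def ri_histogram(
    tomogram: RITomogram,
    mask: np.ndarray,
    bin_width: float,
    value_range: tuple[float, float],
) -> pd.DataFrame:
    """Histogram of RI over masked voxels with half-open bins [lo+kw, lo+(k+1)w).

    Voxels outside *value_range* are ignored; when the range covers all
    masked values the counts sum to the masked voxel count.
    """
    lo, hi = value_range
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    if not lo < hi:
        raise ConfigError(f"invalid range ({lo}, {hi})")
    mask = np.asarray(mask).astype(bool)
    values = tomogram.grid[mask]
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-12))
    counts = np.zeros(n_bins, dtype=np.int64)
    if values.size:
        idx = np.floor((values - lo) / bin_width).astype(np.int64)
        valid = (idx >= 0) & (idx < n_bins)
        counts = np.bincount(idx[valid], minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    return pd.DataFrame({"bin_center": centers, "voxel_count": counts})


def mean_cell_ri(tomogram: RITomogram, mask: np.ndarray) -> float:
    """Arithmetic mean RI over masked voxels; empty masks are an error."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DataError("cannot average RI over an empty mask")
    return float(tomogram.grid[mask].mean())
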