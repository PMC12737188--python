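"""Fluorescence / high-RI colocalization.

The headline figure of merit is the fluorescence-conditional overlap
fraction (Manders-style M1 on binary masks): the percentage of
fluorescence-positive voxels that also belong to the high-RI mask.  The
voxel-level Pearson correlation between raw intensity and raw RI is
reported alongside.  Cells with no fluorescence yield a missing fraction
(None/NaN), never zero, so across-cell means are not biased downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import ConfigError, DataError
from .volume_io import FluorescenceVolume, RITomogram

__all__ = [
    "ColocParams",
    "ColocResult",
    "binarize_fluorescence",
    "colocalize",
    "coloc_per_cell",
]


@dataclass
class ColocParams:
    fluor_threshold_method: str = "otsu"
    fluor_threshold_value: float = 0.0
    scope: str = "within_cells"

    def __post_init__(self) -> None:
        if self.fluor_threshold_method not in ("otsu", "fixed"):
            raise ConfigError(
                f"unknown threshold method {self.fluor_threshold_method!r}"
            )
        if self.fluor_threshold_value < 0:
            raise ConfigError("fixed fluorescence threshold must be >= 0")
        if self.scope not in ("whole_volume", "within_cells"):
            raise ConfigError(f"unknown scope {self.scope!r}")


@dataclass
class ColocResult:
    fluor_voxels: int
    high_ri_voxels: int
    overlap_voxels: int
    fluor_in_high_ri_fraction: float | None  # %, None when no fluor voxels
    high_ri_in_fluor_fraction: float | None  # %, None when no high-RI voxels
    voxel_pearson_r: float  # NaN when raw channels unavailable/degenerate


def _scope_mask(shape, scope: str, cell_labels: np.ndarray | None) -> np.ndarray:
    if scope == "within_cells":
        if cell_labels is None:
            raise ConfigError("scope 'within_cells' requires cell labels")
        return np.asarray(cell_labels) > 0
    return np.ones(shape, dtype=bool)


def binarize_fluorescence(
    volume: FluorescenceVolume,
    params: ColocParams,
    cell_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold a fluorescence volume into a binary mask.

    With the Otsu method the threshold is computed from the within-scope
    nonzero-intensity histogram (256 bins); a voxel is included iff its
    intensity is strictly above the threshold.  If all nonzero in-scope
    intensities are identical, Otsu is degenerate and the mask is simply the
    nonzero voxels.  An all-zero volume yields an empty mask with a warning.
    """
    scope = _scope_mask(volume.shape, params.scope, cell_labels)
    grid = volume.grid
    values = grid[scope & (grid > 0)]
    if values.size == 0:
        warnings.warn("no nonzero fluorescence in scope; empty mask", stacklevel=2)
        return np.zeros(volume.shape, dtype=bool)
    if params.fluor_threshold_method == "fixed":
        thr = params.fluor_threshold_value
    elif values.min() == values.max():
        thr = float(values.min()) / 2.0
    else:
        thr = float(threshold_otsu(values, nbins=256))
    return (grid > thr) & scope


def _pearson_raw(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def colocalize(
    fluor_mask: np.ndarray,
    high_ri_mask: np.ndarray,
    cell_labels: np.ndarray | None = None,
    params: ColocParams | None = None,
    fluorescence: FluorescenceVolume | None = None,
    tomogram: RITomogram | None = None,
) -> ColocResult:
    """Overlap fractions and voxel Pearson between two binary masks.

    ``fluor_in_high_ri_fraction`` = 100·|F∩H|/|F| (the headline metric);
    its converse is reported symmetrically.  Raw-channel Pearson is computed
    over in-scope voxels when the raw volumes are provided.
    """
    fluor_mask = np.asarray(fluor_mask).astype(bool)
    high = np.asarray(high_ri_mask).astype(bool)
    if fluor_mask.shape != high.shape:
        raise DataError("masks must share a shape")
    params = params or ColocParams(scope="whole_volume")
    scope = _scope_mask(fluor_mask.shape, params.scope, cell_labels)

    f = fluor_mask & scope
    h = high & scope
    nf = int(f.sum())
    nh = int(h.sum())
    no = int((f & h).sum())

    pearson = float("nan")
    if fluorescence is not None and tomogram is not None:
        pearson = _pearson_raw(
            fluorescence.grid[scope].ravel(), tomogram.grid[scope].ravel()
        )

    return ColocResult(
        fluor_voxels=nf,
        high_ri_voxels=nh,
        overlap_voxels=no,
        fluor_in_high_ri_fraction=(100.0 * no / nf) if nf else None,
        high_ri_in_fluor_fraction=(100.0 * no / nh) if nh else None,
        voxel_pearson_r=pearson,
    )


def coloc_per_cell(
    fluor_mask: np.ndarray,
    high_ri_mask: np.ndarray,
    cell_labels: np.ndarray,
    fluorescence: FluorescenceVolume | None = None,
    tomogram: RITomogram | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell colocalization plus a mean ± SD summary.

    Cells without fluorescence contribute missing fractions and are excluded
    from the summary mean/SD.  Also returns the pooled (voxel-weighted)
    fraction across all cells.
    """
    cell_labels = np.asarray(cell_labels)
    ids = np.unique(cell_labels)
    ids = ids[ids > 0]
    rows = []
    for cid in ids:
        cmask = cell_labels == cid
        f = np.asarray(fluor_mask, dtype=bool) & cmask
        h = np.asarray(high_ri_mask, dtype=bool) & cmask
        nf, nh, no = int(f.sum()), int(h.sum()), int((f & h).sum())
        pearson = float("nan")
        if fluorescence is not None and tomogram is not None:
            pearson = _pearson_raw(fluorescence.grid[cmask], tomogram.grid[cmask])
        rows.append(
            {
                "cell_id": int(cid),
                "fluor_voxels": nf,
                "high_ri_voxels": nh,
                "overlap_voxels": no,
                "fluor_in_high_ri_fraction": (100.0 * no / nf) if nf else np.nan,
                "high_ri_in_fluor_fraction": (100.0 * no / nh) if nh else np.nan,
                "voxel_pearson_r": pearson,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "fluor_voxels",
            "high_ri_voxels",
            "overlap_voxels",
            "fluor_in_high_ri_fraction",
            "high_ri_in_fluor_fraction",
            "voxel_pearson_r",
        ],
    )
    valid = table["fluor_in_high_ri_fraction"].dropna()
    tot_f = int(table["fluor_voxels"].sum())
    tot_o = int(table["overlap_voxels"].sum())
    summary = {
        "n_cells": int(len(table)),
        "n_cells_with_fluorescence": int(valid.size),
        "mean_fluor_in_high_ri_fraction": float(valid.mean()) if valid.size else None,
        "sd_fluor_in_high_ri_fraction": (
            float(valid.std(ddof=1)) if valid.size > 1 else None
        ),
        "pooled_fluor_in_high_ri_fraction": (
            100.0 * tot_o / tot_f if tot_f else None
        ),
    }
    return table, summary
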