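"""Volume and table I/O.

3D volumes are numpy arrays indexed ``(z, y, x)`` stored as multi-page TIFF
stacks (one page per z-slice, z ascending).  Physical voxel size is carried in
a YAML sidecar (``<path>.yaml`` with key ``spacing_um: [dz, dy, dx]``) rather
than in TIFF tags, because holotomography vendors disagree on tag dialects.

Tabular results are plain comma-separated text with a header row; floats are
written with 12 significant digits so round-trips are lossless for practical
purposes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError

__all__ = [
    "VoxelSpacing",
    "RITomogram",
    "FluorescenceVolume",
    "read_volume",
    "write_volume",
    "read_spacing",
    "write_spacing",
    "read_ri_tomogram",
    "read_fluorescence",
    "write_labels",
    "read_labels",
    "read_table",
    "write_table",
    "validate_label_volume",
]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in µm per axis, ordered (dz, dy, dx)."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DataError(f"voxel spacing {name}={v!r} must be finite and > 0")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dz * self.dy * self.dx

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


def _validate_grid(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 3:
        raise DataError(f"{name} must be a 3D (z, y, x) array, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


@dataclass
class RITomogram:
    """3D refractive-index grid with physical voxel spacing.

    RI values are dimensionless and must lie in [1.0, 2.0], a physical
    plausibility gate for biological samples in aqueous media.
    """

    grid: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.grid = _validate_grid(self.grid, "RI grid")
        lo, hi = float(self.grid.min(initial=1.0)), float(self.grid.max(initial=1.0))
        if lo < 1.0 or hi > 2.0:
            raise DataError(
                f"RI values outside plausible range [1.0, 2.0]: min={lo}, max={hi}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class FluorescenceVolume:
    """Co-registered 3D fluorescence intensity grid (arbitrary units ≥ 0)."""

    grid: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.grid = _validate_grid(self.grid, "fluorescence grid")
        if self.grid.size and float(self.grid.min()) < 0:
            raise DataError("fluorescence intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def validate_label_volume(labels: np.ndarray) -> np.ndarray:
    """Check a label volume: non-negative ints, contiguous label set {0..K}."""
    arr = np.asarray(labels)
    if arr.ndim != 3:
        raise DataError("label volume must be 3D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise DataError("label volume must have an integer dtype")
    if arr.size and arr.min() < 0:
        raise DataError("labels must be non-negative")
    present = np.unique(arr)
    nonzero = present[present > 0]
    if nonzero.size and not np.array_equal(nonzero, np.arange(1, nonzero.size + 1)):
        raise DataError("label set must be contiguous 1..K")
    return arr


# ---------------------------------------------------------------------------
# volumes


def _sidecar_path(path: str | os.PathLike) -> str:
    return f"{os.fspath(path)}.yaml"


def read_volume(path: str | os.PathLike) -> np.ndarray:
    """Read a multi-page TIFF into a (nz, ny, nx) array.

    Values are preserved bit-exactly for floating-point pages.  A single-page
    file yields nz = 1.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tf_ctx = tifffile.TiffFile(path)
    except Exception as exc:
        raise DataError(f"cannot read {path} as TIFF: {exc}") from exc
    with tf_ctx as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise DataError(f"ragged TIFF pages, shapes {sorted(shapes)}: {path}")
        dtypes = {p.dtype for p in tf.pages}
        if any(d is None or not np.issubdtype(d, np.number) for d in dtypes):
            raise DataError(f"non-numeric pixel type in {path}")
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise DataError(f"expected a z-stack of 2D pages, got shape {arr.shape}")
    return arr


def write_volume(
    values: np.ndarray,
    path: str | os.PathLike,
    spacing: VoxelSpacing | None = None,
) -> str:
    """Write a (nz, ny, nx) array as a multi-page TIFF, z ascending.

    If *spacing* is given it is recorded in a YAML sidecar next to the file.
    """
    arr = np.asarray(values)
    if arr.ndim != 3:
        raise DataError(f"expected 3D volume, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating) and arr.dtype != np.float32:
        arr = arr.astype(np.float32) if arr.dtype.itemsize < 4 else arr
    tifffile.imwrite(os.fspath(path), arr, photometric="minisblack")
    if spacing is not None:
        write_spacing(path, spacing)
    return os.fspath(path)


def write_spacing(volume_path: str | os.PathLike, spacing: VoxelSpacing) -> str:
    sidecar = _sidecar_path(volume_path)
    with open(sidecar, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"spacing_um": [spacing.dz, spacing.dy, spacing.dx]}, fh)
    return sidecar


def read_spacing(volume_path: str | os.PathLike) -> VoxelSpacing:
    sidecar = _sidecar_path(volume_path)
    if not os.path.exists(sidecar):
        raise DataError(f"no spacing sidecar found: {sidecar}")
    with open(sidecar, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    try:
        dz, dy, dx = meta["spacing_um"]
    except (KeyError, TypeError, ValueError) as exc:
        raise DataError(f"malformed sidecar {sidecar}: {exc}") from exc
    return VoxelSpacing(float(dz), float(dy), float(dx))


def read_ri_tomogram(
    path: str | os.PathLike, spacing: VoxelSpacing | None = None
) -> RITomogram:
    """Read an RI tomogram; spacing from the sidecar unless supplied."""
    if spacing is None:
        spacing = read_spacing(path)
    return RITomogram(read_volume(path), spacing)


def read_fluorescence(
    path: str | os.PathLike, spacing: VoxelSpacing | None = None
) -> FluorescenceVolume:
    if spacing is None:
        spacing = read_spacing(path)
    return FluorescenceVolume(read_volume(path), spacing)


def write_labels(
    labels: np.ndarray, path: str | os.PathLike, spacing: VoxelSpacing | None = None
) -> str:
    """Write an integer label volume as a uint32 multi-page TIFF."""
    arr = np.asarray(labels)
    if arr.size and (arr.min() < 0 or arr.max() > np.iinfo(np.uint32).max):
        raise DataError("labels out of uint32 range")
    return write_volume(arr.astype(np.uint32), path, spacing)


def read_labels(path: str | os.PathLike) -> np.ndarray:
    arr = read_volume(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise DataError(f"label volume {path} is not integer-typed")
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# tables


def write_table(records, path: str | os.PathLike) -> str:
    """Write records (DataFrame, or iterable of dicts/dataclasses) as CSV."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append(
                    {k: getattr(rec, k) for k in rec.__dataclass_fields__}
                )
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    df.to_csv(os.fspath(path), index=False, float_format="%.12g")
    return os.fspath(path)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed table {path}: {exc}") from exc
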