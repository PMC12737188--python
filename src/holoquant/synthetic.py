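"""Synthetic tomogram generator with exact ground truth.

Generates paired refractive-index (RI) tomograms and fluorescence volumes
containing non-overlapping ellipsoidal cells, spherical high-RI aggregates
(fluorescent) and lipid-droplet confounders (non-fluorescent), with the
statistical structure the downstream analysis assumes:

* background RI strictly below the 1.34 cell threshold, cytoplasm strictly
  between 1.34 and 1.36, aggregates and droplets strictly above 1.36 — so
  with zero noise the two thresholds recover ground truth exactly;
* aggregate volumes drawn lognormal (defaults reproduce an arithmetic mean
  of ~0.55 µm³ and SD ~0.50 µm³);
* per-cell aggregate counts drawn as a rounded Gaussian floored at 0
  (default 50 ± 45);
* a tunable positive association between cell volume and total aggregate
  load, induced through a Gaussian-copula mixture (see
  :func:`induce_uptake_association`);
* fluorescence strictly confined to fluorophore-bearing aggregate voxels
  plus an optional dispersed sub-threshold-RI component, whose weight sets
  the expected fluorescence/high-RI colocalization fraction to
  ``1 - sub_threshold_fluor_fraction``.

All randomness flows from a single seed through per-cell sub-streams, so an
identical configuration is bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ConfigError, DataError
from .volume_io import FluorescenceVolume, RITomogram, VoxelSpacing

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "induce_uptake_association",
    "lognormal_params_from_moments",
    "lognormal_moments",
]

_MAX_PLACEMENT_TRIES = 500
_MAX_SPHERE_TRIES = 2000


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Natural-log (mu, sigma) of a lognormal with given arithmetic mean/SD."""
    if mean <= 0 or sd < 0:
        raise ConfigError("lognormal moments require mean > 0, sd >= 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def lognormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Arithmetic (mean, SD) of lognormal(mu, sigma)."""
    mean = math.exp(mu + sigma**2 / 2.0)
    sd = mean * math.sqrt(math.expm1(sigma**2))
    return mean, sd


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``cell_radius_um`` is the (mean, SD) of a Gaussian from which each
    ellipsoid semi-axis is drawn independently.  RI intervals are sampled
    uniformly.  ``aggregates_per_cell`` parameterizes the rounded Gaussian
    count (floored at 0); ``aggregate_volume_lognormal`` holds natural-log
    (mu, sigma) of the per-aggregate volume in µm³.
    """

    shape: tuple[int, int, int] = (64, 160, 160)
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(0.5, 0.2, 0.2))
    n_cells: int = 3
    cell_radius_um: tuple[float, float] = (6.0, 0.6)
    ri_background: float = 1.330
    ri_cytoplasm: tuple[float, float] = (1.340, 1.358)
    ri_aggregate: tuple[float, float] = (1.370, 1.420)
    ri_droplet: tuple[float, float] = (1.370, 1.490)
    aggregates_per_cell: tuple[float, float] = (50.0, 45.0)
    aggregate_volume_lognormal: tuple[float, float] = (-0.90, 0.78)
    droplets_per_cell: float = 2.0
    uptake_association: float = 0.35
    fluorophore_fraction: float = 1.0
    sub_threshold_fluor_fraction: float = 0.0
    noise_sd_ri: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.shape
        if min(nz, ny, nx) < 1:
            raise ConfigError(f"invalid shape {self.shape}")
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if not self.ri_background < 1.34 <= self.ri_cytoplasm[0]:
            raise ConfigError(
                "need ri_background < 1.34 <= ri_cytoplasm.low for threshold recovery"
            )
        if self.ri_cytoplasm[1] >= 1.36:
            raise ConfigError("cytoplasm RI must stay strictly below 1.36")
        if self.ri_aggregate[0] <= 1.36:
            raise ConfigError("aggregate RI must be strictly above 1.36")
        for name in ("ri_cytoplasm", "ri_aggregate", "ri_droplet"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigError(f"{name} interval must be ordered, got ({lo}, {hi})")
        for name in ("fluorophore_fraction", "sub_threshold_fluor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.sub_threshold_fluor_fraction >= 1.0:
            raise ConfigError("sub_threshold_fluor_fraction must be < 1")
        if not -1.0 < self.uptake_association < 1.0:
            raise ConfigError("uptake_association must be in (-1, 1)")
        if self.cell_radius_um[0] <= 0 or self.cell_radius_um[1] < 0:
            raise ConfigError("cell_radius_um mean must be > 0, SD >= 0")
        if self.noise_sd_ri < 0:
            raise ConfigError("noise_sd_ri must be >= 0")
        if self.droplets_per_cell < 0:
            raise ConfigError("droplets_per_cell must be >= 0")
        # feasibility: expected total cell volume must leave room to place
        grid_um3 = (
            nz * self.spacing.dz * ny * self.spacing.dy * nx * self.spacing.dx
        )
        expected_cell = 4.0 / 3.0 * math.pi * self.cell_radius_um[0] ** 3
        if self.n_cells * expected_cell > 0.60 * grid_um3:
            raise ConfigError(
                f"expected total cell volume {self.n_cells * expected_cell:.0f} µm³ "
                f"exceeds 60% of the grid ({grid_um3:.0f} µm³)"
            )


@dataclass
class GroundTruth:
    """Exact object-level truth for one generated scene."""

    cell_labels: np.ndarray
    aggregate_labels: np.ndarray
    droplet_labels: np.ndarray
    per_aggregate: pd.DataFrame
    per_cell: pd.DataFrame


def induce_uptake_association(
    cell_volumes,
    target_r: float,
    seed,
    count_mean: float = 50.0,
    count_sd: float = 45.0,
) -> np.ndarray:
    """Per-cell load multipliers inducing corr(cell volume, NP load) ≈ target_r.

    Gaussian-copula mixture: the latent load score of cell *i* is
    ``z_i = target_r * s_i + sqrt(1 - target_r²) * e_i`` where ``s_i`` is the
    normal score of the cell-volume rank and ``e_i`` is independent standard
    normal.  The returned multiplier ``m_i = max(0, count_mean + count_sd*z_i)
    / count_mean`` makes ``round(count_mean * m_i)`` marginally a rounded
    Gaussian floored at 0 while carrying the target rank correlation with
    volume.  Truncation at 0 attenuates the realized correlation slightly
    (a few percent at target 0.35).
    """
    vols = np.asarray(cell_volumes, dtype=float)
    n = vols.size
    if n < 3:
        raise DataError("need at least 3 cells to induce an association")
    if not -1.0 < target_r < 1.0:
        raise ConfigError(f"target_r must be in (-1, 1), got {target_r}")
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    if np.ptp(vols) == 0.0:
        warnings.warn(
            "all cell volumes equal; returning volume-independent loads",
            stacklevel=2,
        )
        z = e
    else:
        # flooring the count at 0 attenuates corr(load, volume) by
        # corr(max(0, mu + sd*z), z) = sd*Phi(mu/sd) / SD_censored; inflate
        # the copula weight by that factor so the realized correlation hits
        # the target in expectation
        alpha = count_mean / count_sd if count_sd > 0 else math.inf
        if math.isfinite(alpha):
            ez = count_mean * norm.cdf(alpha) + count_sd * norm.pdf(alpha)
            ez2 = (count_mean**2 + count_sd**2) * norm.cdf(
                alpha
            ) + count_mean * count_sd * norm.pdf(alpha)
            sd_cens = math.sqrt(max(ez2 - ez**2, 1e-12))
            atten = count_sd * norm.cdf(alpha) / sd_cens
        else:
            atten = 1.0
        rho = max(-0.999, min(0.999, target_r / atten))
        # Blom normal scores of the volume ranks, standardized to unit SD
        # (for small n their raw SD is well below 1, which would attenuate
        # the induced correlation)
        s = norm.ppf((rankdata(vols) - 0.375) / (n + 0.25))
        s = s / s.std(ddof=0)
        z = rho * s + math.sqrt(1.0 - rho**2) * e
    return np.maximum(0.0, count_mean + count_sd * z) / count_mean


# ---------------------------------------------------------------------------
# rendering helpers (voxel center of index k sits at (k + 0.5) * d µm)


def _ellipsoid_mask_bbox(shape, spacing, center_um, semi_um):
    """Bounding-box slices and boolean ellipsoid mask within them."""
    d = np.array(spacing.as_tuple())
    lo = np.maximum(0, np.floor((center_um - semi_um) / d - 0.5).astype(int))
    hi = np.minimum(shape, np.ceil((center_um + semi_um) / d + 0.5).astype(int) + 1)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    coords = [
        (np.arange(s.start, s.stop) + 0.5) * dd for s, dd in zip(sl, d)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    q = (
        ((zz - center_um[0]) / semi_um[0]) ** 2
        + ((yy - center_um[1]) / semi_um[1]) ** 2
        + ((xx - center_um[2]) / semi_um[2]) ** 2
    )
    return sl, q <= 1.0


def _sphere_mask_bbox(shape, spacing, center_um, radius_um):
    r = np.array([radius_um] * 3)
    return _ellipsoid_mask_bbox(shape, spacing, center_um, r)


def _place_cells(cfg: SceneConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping ellipsoid centers/semi-axes, in µm."""
    nz, ny, nx = cfg.shape
    extent = np.array(
        [nz * cfg.spacing.dz, ny * cfg.spacing.dy, nx * cfg.spacing.dx]
    )
    max_sp = max(cfg.spacing.as_tuple())
    mean_r, sd_r = cfg.cell_radius_um
    centers = np.zeros((cfg.n_cells, 3))
    semis = np.zeros((cfg.n_cells, 3))
    for i in range(cfg.n_cells):
        semi = np.maximum(rng.normal(mean_r, sd_r, size=3), 2.0 * max_sp)
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            margin = semi + max_sp
            if np.any(extent - 2 * margin <= 0):
                continue
            c = rng.uniform(margin, extent - margin)
            ok = True
            for j in range(i):
                if np.linalg.norm(c - centers[j]) <= (
                    semi.max() + semis[j].max() + 2.0 * max_sp
                ):
                    ok = False
                    break
            if ok:
                centers[i], semis[i] = c, semi
                placed = True
                break
        if not placed:
            raise DataError(
                f"could not place cell {i + 1}/{cfg.n_cells} after "
                f"{_MAX_PLACEMENT_TRIES} tries; grid too crowded"
            )
    return centers, semis


def _place_sphere_in_cell(rng, center_um, semi_um, radius_um, occupied, min_gap):
    """Random sphere center inside an ellipsoid, clear of occupied spheres.

    Returns the center or None when no admissible position is found.
    """
    shrink = semi_um - radius_um - min_gap / 2.0
    if np.any(shrink <= 0):
        return None
    for _ in range(_MAX_SPHERE_TRIES):
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) > 1.0:
            continue
        c = center_um + u * shrink
        ok = True
        for oc, orad in occupied:
            if np.linalg.norm(c - oc) <= radius_um + orad + min_gap:
                ok = False
                break
        if ok:
            return c
    return None


def generate_scene(
    config: SceneConfig,
) -> tuple[RITomogram, FluorescenceVolume, GroundTruth]:
    """Render one scene; identical config (incl. seed) is bit-reproducible."""
    config.validate()
    cfg = config
    shape = tuple(cfg.shape)
    sp = cfg.spacing
    vv = sp.voxel_volume
    max_sp = max(sp.as_tuple())

    root = np.random.SeedSequence(cfg.seed)
    scene_ss, *cell_ss = root.spawn(1 + max(cfg.n_cells, 1))
    rng = np.random.default_rng(scene_ss)

    ri = np.full(shape, cfg.ri_background, dtype=np.float64)
    fluor = np.zeros(shape, dtype=np.float64)
    cell_labels = np.zeros(shape, dtype=np.int32)
    agg_labels = np.zeros(shape, dtype=np.int32)
    drop_labels = np.zeros(shape, dtype=np.int32)

    agg_rows: list[dict] = []
    cell_rows: list[dict] = []

    if cfg.n_cells > 0:
        centers, semis = _place_cells(cfg, rng)
        cell_vox = np.zeros(cfg.n_cells, dtype=np.int64)
        cell_masks = []
        for i in range(cfg.n_cells):
            crng = np.random.default_rng(cell_ss[i])
            sl, mask = _ellipsoid_mask_bbox(shape, sp, centers[i], semis[i])
            cell_labels[sl][mask] = i + 1
            cyto = crng.uniform(*cfg.ri_cytoplasm)
            ri[sl][mask] = cyto
            # nucleus: slightly lower-RI inclusion, still >= 1.34 so the
            # foreground threshold sees an unbroken cell
            nsl, nmask = _ellipsoid_mask_bbox(shape, sp, centers[i], 0.4 * semis[i])
            ri[nsl][nmask] = max(1.340, cyto - 0.004)
            cell_vox[i] = int(mask.sum())
            cell_masks.append((sl, mask))

        cell_vol_um3 = cell_vox * vv
        mu_ln, sig_ln = cfg.aggregate_volume_lognormal
        cmean, csd = cfg.aggregates_per_cell
        if cfg.n_cells >= 3 and np.ptp(cell_vol_um3) > 0:
            multipliers = induce_uptake_association(
                cell_vol_um3,
                cfg.uptake_association,
                scene_ss.spawn(1)[0],
                count_mean=cmean,
                count_sd=csd,
            )
        else:
            z = rng.standard_normal(cfg.n_cells)
            multipliers = np.maximum(0.0, cmean + csd * z) / cmean

        # two voxels are 26-adjacent only if their centers are within the
        # voxel diagonal, so this gap guarantees separated components
        min_gap = 1.05 * math.sqrt(sp.dz**2 + sp.dy**2 + sp.dx**2)
        agg_id = 0
        drop_id = 0
        for i in range(cfg.n_cells):
            crng = np.random.default_rng(cell_ss[i].spawn(1)[0])
            n_agg = int(round(cmean * multipliers[i]))
            n_drop = int(crng.poisson(cfg.droplets_per_cell))
            occupied: list[tuple[np.ndarray, float]] = []
            total_np_um3 = 0.0
            n_placed = 0
            # draw all target volumes up front and place largest-first;
            # sequential placement jams when a big sphere arrives late in a
            # crowded cell, while the reverse order leaves small spheres to
            # fill the remaining gaps (marginal distributions unchanged)
            agg_targets = crng.lognormal(mu_ln, sig_ln, size=n_agg)
            drop_targets = crng.lognormal(mu_ln, sig_ln, size=n_drop)
            items = sorted(
                [("agg", float(v)) for v in agg_targets]
                + [("drop", float(v)) for v in drop_targets],
                key=lambda kv: -kv[1],
            )
            for kind, target_v in items:
                radius = (3.0 * target_v / (4.0 * math.pi)) ** (1.0 / 3.0)
                c = _place_sphere_in_cell(
                    crng, centers[i], semis[i], radius, occupied, min_gap
                )
                if c is None:
                    raise DataError(
                        f"could not place {kind} of {target_v:.3g} µm³ in "
                        f"cell {i + 1}; reduce load or enlarge cells"
                    )
                occupied.append((c, radius))
                sl, mask = _sphere_mask_bbox(shape, sp, c, radius)
                if not mask.any():
                    # sub-voxel sphere between grid points: keep its voxel
                    idx = tuple(
                        int(np.clip(c[k] / sp.as_tuple()[k], 0, shape[k] - 1))
                        for k in range(3)
                    )
                    sl = tuple(slice(j, j + 1) for j in idx)
                    mask = np.ones((1, 1, 1), dtype=bool)
                nvox = int(mask.sum())
                if kind == "agg":
                    agg_id += 1
                    n_placed += 1
                    agg_labels[sl][mask] = agg_id
                    ri[sl][mask] = crng.uniform(*cfg.ri_aggregate)
                    fluorescent = bool(crng.random() < cfg.fluorophore_fraction)
                    if fluorescent:
                        fluor[sl][mask] = np.maximum(
                            crng.normal(1000.0, 100.0, size=nvox), 1.0
                        )
                    total_np_um3 += nvox * vv
                    agg_rows.append(
                        {
                            "id": agg_id,
                            "cell_id": i + 1,
                            "voxel_count": nvox,
                            "true_volume_um3": nvox * vv,
                            "target_volume_um3": target_v,
                            "fluorescent": fluorescent,
                        }
                    )
                else:
                    drop_id += 1
                    drop_labels[sl][mask] = drop_id
                    ri[sl][mask] = crng.uniform(*cfg.ri_droplet)
            cell_rows.append(
                {
                    "id": i + 1,
                    "true_volume_um3": cell_vox[i] * vv,
                    "true_total_np_volume_um3": total_np_um3,
                    "true_aggregate_count": n_placed,
                }
            )

        # dispersed sub-threshold fluorescence: a fraction f of the total
        # fluorescent volume sits in cytoplasm voxels below the high-RI
        # threshold, so the expected colocalization fraction is 1 - f
        f = cfg.sub_threshold_fluor_fraction
        n_fluor_vox = int(np.count_nonzero(fluor))
        if f > 0 and n_fluor_vox > 0:
            n_disp = int(round(f / (1.0 - f) * n_fluor_vox))
            candidates = np.flatnonzero(
                (cell_labels > 0) & (agg_labels == 0) & (drop_labels == 0)
            )
            if n_disp > candidates.size:
                raise DataError("not enough cytoplasm voxels for dispersed signal")
            if n_disp > 0:
                chosen = rng.choice(candidates, size=n_disp, replace=False)
                fluor.ravel()[chosen] = np.maximum(
                    rng.normal(1000.0, 100.0, size=n_disp), 1.0
                )

    if cfg.noise_sd_ri > 0:
        ri += rng.normal(0.0, cfg.noise_sd_ri, size=shape)

    per_aggregate = pd.DataFrame(
        agg_rows,
        columns=[
            "id",
            "cell_id",
            "voxel_count",
            "true_volume_um3",
            "target_volume_um3",
            "fluorescent",
        ],
    )
    per_cell = pd.DataFrame(
        cell_rows,
        columns=[
            "id",
            "true_volume_um3",
            "true_total_np_volume_um3",
            "true_aggregate_count",
        ],
    )
    truth = GroundTruth(cell_labels, agg_labels, drop_labels, per_aggregate, per_cell)
    return RITomogram(ri, sp), FluorescenceVolume(fluor, sp), truth


def scene_config_from_dict(d: dict) -> SceneConfig:
    """Build a SceneConfig from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    if "spacing" in d and not isinstance(d["spacing"], VoxelSpacing):
        d["spacing"] = VoxelSpacing(*[float(v) for v in d["spacing"]])
    if "shape" in d:
        d["shape"] = tuple(int(v) for v in d["shape"])
    for key in (
        "cell_radius_um",
        "ri_cytoplasm",
        "ri_aggregate",
        "ri_droplet",
        "aggregates_per_cell",
        "aggregate_volume_lognormal",
    ):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    unknown = set(d) - set(SceneConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown scene config keys: {sorted(unknown)}")
    return replace(SceneConfig(), **d)


def scene_config_to_dict(cfg: SceneConfig) -> dict:
    d = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    d["spacing"] = list(cfg.spacing.as_tuple())
    d["shape"] = list(cfg.shape)
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
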