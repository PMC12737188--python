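"""Statistics layer: correlations, group comparisons, distribution fits,
and assembly of the per-study summary report.

Pearson significance uses the exact t transform, t = r·sqrt(n−2)/sqrt(1−r²),
with a two-tailed p from the Student-t distribution on n−2 degrees of
freedom (α = 0.05 by default).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ConfigError, DataError

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "GaussianFit",
    "SummaryReport",
    "pearson",
    "p_from_r",
    "compare_groups",
    "fit_gaussian",
    "build_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_two_tailed: float
    alpha: float = 0.05
    significant: bool = False


@dataclass
class GroupComparisonResult:
    test: str  # "t" or "anova"
    statistic: float
    df: tuple
    p_two_tailed: float
    group_means: list[float] = field(default_factory=list)
    group_sds: list[float] = field(default_factory=list)


@dataclass
class GaussianFit:
    mean: float
    sd_ml: float       # population SD, n denominator (maximum likelihood)
    sd_sample: float   # n-1 denominator
    n: int


def p_from_r(r, n):
    """Two-tailed p of a Pearson r via the t transform (df = n−2).

    Vectorized over r; |r| = 1 maps to p = 0 by convention.
    """
    r_arr = np.asarray(r, dtype=float)
    n = int(n)
    if n < 3:
        raise DataError("p_from_r requires n >= 3")
    if np.any(np.abs(r_arr) > 1):
        raise DataError("|r| cannot exceed 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r_arr) * np.sqrt((n - 2) / (1.0 - r_arr**2))
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, 2.0 * sps.t.sf(t, df=n - 2))
    return float(p) if np.isscalar(r) or r_arr.ndim == 0 else p


def pearson(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Product-moment correlation with two-tailed t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1D and paired")
    n = x.size
    if n < 3:
        raise DataError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise DataError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        t_stat, p = math.inf, 0.0
    else:
        t_stat = r * math.sqrt((n - 2) / (1.0 - r**2))
        p = float(p_from_r(r, n))
    return CorrelationResult(
        r=r, n=n, t_stat=t_stat, p_two_tailed=p, alpha=alpha, significant=p < alpha
    )


def compare_groups(
    groups, test: str = "t", equal_var: bool = True
) -> GroupComparisonResult:
    """Two-sample Student t (pooled variance by default) or one-way ANOVA."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if test == "t":
        if len(arrays) != 2:
            raise ConfigError("t-test requires exactly 2 groups")
        if any(a.size < 2 for a in arrays):
            raise DataError("each group needs n >= 2")
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        if equal_var:
            df = (arrays[0].size + arrays[1].size - 2,)
        else:
            df = (float(res.df),)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "anova":
        if len(arrays) < 2:
            raise ConfigError("ANOVA requires >= 2 groups")
        if any(a.size < 2 for a in arrays):
            raise DataError("each group needs n >= 2")
        res = sps.f_oneway(*arrays)
        k = len(arrays)
        n_tot = sum(a.size for a in arrays)
        df = (k - 1, n_tot - k)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigError(f"unknown test {test!r}")
    return GroupComparisonResult(
        test=test,
        statistic=stat,
        df=df,
        p_two_tailed=p,
        group_means=[float(a.mean()) for a in arrays],
        group_sds=[float(a.std(ddof=1)) for a in arrays],
    )


def fit_gaussian(samples) -> GaussianFit:
    """Maximum-likelihood Gaussian fit (mean and both SD conventions)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DataError("Gaussian fit needs n >= 2")
    return GaussianFit(
        mean=float(x.mean()),
        sd_ml=float(x.std(ddof=0)),
        sd_sample=float(x.std(ddof=1)),
        n=int(x.size),
    )


def _mean_sd_block(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {"mean": None, "sd": None, "n": 0}
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else None,
        "n": int(values.size),
    }


def _corr_or_none(x, y, alpha) -> dict | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return None
    return asdict(pearson(x, y, alpha=alpha))


@dataclass
class SummaryReport:
    """Aggregated uptake report: summary moments, correlations, histograms."""

    schema_version: int
    uptake_block: dict
    correlations_block: dict
    histograms_block: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _as_dataframe(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {k: getattr(r, k) for k in r.__dataclass_fields__}
        if hasattr(r, "__dataclass_fields__")
        else dict(r)
        for r in records
    ]
    return pd.DataFrame(rows, columns=columns)


def build_report(
    cells,
    aggregates,
    coloc_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
    size_cutoff_um3: float = 1.0,
) -> SummaryReport:
    """Assemble the summary report from per-cell stats, aggregate records,
    and an optional per-cell colocalization table.

    Deterministic: identical inputs yield an identical report.  Cells with
    zero aggregates count toward the count/fraction summaries (as 0) but are
    excluded from the mean-aggregate-size vs RI correlation, where their
    mean size is undefined.  Empty inputs produce explicit missing fields.
    """
    cells_df = _as_dataframe(
        cells,
        [
            "cell_id",
            "cell_volume_um3",
            "mean_cell_ri",
            "aggregate_count",
            "total_np_volume_um3",
            "np_volume_fraction",
            "mean_aggregate_volume_um3",
        ],
    )
    agg_df = _as_dataframe(
        aggregates,
        ["id", "cell_id", "voxel_count", "volume_um3", "mean_ri", "max_ri", "centroid"],
    )

    coloc_block = {"mean": None, "sd": None, "n": 0, "pooled": None}
    if coloc_table is not None and len(coloc_table):
        frac = coloc_table["fluor_in_high_ri_fraction"].astype(float)
        coloc_block = _mean_sd_block(frac.to_numpy())
        tot_f = float(coloc_table["fluor_voxels"].sum())
        tot_o = float(coloc_table["overlap_voxels"].sum())
        coloc_block["pooled"] = 100.0 * tot_o / tot_f if tot_f else None

    agg_vols = (
        agg_df["volume_um3"].to_numpy(dtype=float) if len(agg_df) else np.array([])
    )
    uptake_block = {
        "colocalization_pct": coloc_block,
        "aggregate_volume_um3": _mean_sd_block(agg_vols),
        "np_volume_fraction_pct": _mean_sd_block(
            cells_df["np_volume_fraction"].to_numpy(dtype=float)
            if len(cells_df)
            else np.array([])
        ),
        "aggregates_per_cell": _mean_sd_block(
            cells_df["aggregate_count"].to_numpy(dtype=float)
            if len(cells_df)
            else np.array([])
        ),
        "n_cells": int(len(cells_df)),
        "n_aggregates": int(len(agg_df)),
    }

    correlations_block = {
        "cell_volume_vs_np_volume": None,
        "np_volume_vs_mean_ri": None,
        "mean_aggregate_volume_vs_mean_ri": None,
    }
    if len(cells_df) >= 3:
        correlations_block["cell_volume_vs_np_volume"] = _corr_or_none(
            cells_df["cell_volume_um3"], cells_df["total_np_volume_um3"], alpha
        )
        correlations_block["np_volume_vs_mean_ri"] = _corr_or_none(
            cells_df["total_np_volume_um3"], cells_df["mean_cell_ri"], alpha
        )
        with_aggs = cells_df[cells_df["aggregate_count"] > 0]
        correlations_block["mean_aggregate_volume_vs_mean_ri"] = _corr_or_none(
            with_aggs["mean_aggregate_volume_um3"], with_aggs["mean_cell_ri"], alpha
        )

    histograms_block = {"aggregates_per_cell": None, "aggregate_sizes": None}
    counts = cells_df["aggregate_count"].to_numpy(dtype=float) if len(cells_df) else []
    if len(counts) >= 2:
        fit = fit_gaussian(counts)
        histograms_block["aggregates_per_cell"] = {
            "gaussian_fit_mean": fit.mean,
            "gaussian_fit_sd": fit.sd_sample,
            "n": fit.n,
        }
    if len(agg_vols):
        from .aggregates import aggregate_size_distribution

        hist, cum, frac_below = aggregate_size_distribution(
            agg_vols, cutoff_um3=size_cutoff_um3
        )
        histograms_block["aggregate_sizes"] = {
            "bin_center_um3": hist["bin_center_um3"].tolist(),
            "count": hist["count"].tolist(),
            "cumulative_pct": cum["cumulative_pct"].tolist(),
            "fraction_below_cutoff_pct": frac_below,
            "cutoff_um3": size_cutoff_um3,
        }

    return SummaryReport(
        schema_version=REPORT_SCHEMA_VERSION,
        uptake_block=uptake_block,
        correlations_block=correlations_block,
        histograms_block=histograms_block,
    )
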