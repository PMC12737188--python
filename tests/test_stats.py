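import math

import numpy as np
import pytest
import scipy.stats as sps
from scipy.integrate import quad

from holoquant.aggregates import CellStats
from holoquant.errors import ConfigError, DataError
from holoquant.stats import (
    build_report,
    compare_groups,
    fit_gaussian,
    p_from_r,
    pearson,
)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(0.0, abs=1e-30)
        assert res.significant

    def test_reference_nonsignificant_pair(self):
        # r = 0.0942 at n = 230 reports as p = 0.155
        p = p_from_r(0.0942, 230)
        assert abs(round(p, 3) - 0.155) <= 0.001 + 1e-12

    def test_reference_significant_pair(self):
        assert p_from_r(0.3534, 230) < 1e-4

    def test_t_stat_identity(self, rng):
        x = rng.random(30)
        y = x + rng.random(30)
        res = pearson(x, y)
        expected_t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.t_stat == pytest.approx(expected_t)

    def test_matches_scipy(self, rng):
        x = rng.random(50)
        y = rng.random(50)
        res = pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_is_error(self):
        with pytest.raises(DataError, match="zero-variance"):
            pearson(np.ones(10), np.arange(10.0))


class TestPFromR:
    def test_r_zero_gives_one(self):
        assert p_from_r(0.0, 10) == pytest.approx(1.0)

    def test_r_one_gives_zero(self):
        assert p_from_r(1.0, 10) == 0.0

    def test_monotone_decreasing_in_abs_r(self):
        rs = np.linspace(0.0, 0.95, 20)
        ps = p_from_r(rs, 50)
        assert (np.diff(ps) < 0).all()

    @pytest.mark.parametrize("n", [10, 50, 230])
    def test_numerical_integration_oracle(self, n):
        # independent oracle: integrate the t density directly
        for r in np.arange(0.05, 0.96, 0.10):
            t = r * math.sqrt((n - 2) / (1 - r**2))
            dens = sps.t(df=n - 2).pdf
            tail, _ = quad(dens, t, np.inf)
            assert p_from_r(r, n) == pytest.approx(2 * tail, abs=1e-6)

    def test_type_i_error_calibrated(self):
        # under the null, two-tailed test at alpha=0.05 rejects ~5%
        rng = np.random.default_rng(2024)
        reps, n = 10_000, 50
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        ps = p_from_r(r, n)
        rate = (ps < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.006)

    def test_vectorized_matches_scalar(self):
        rs = np.array([0.1, 0.5, 0.9])
        vec = p_from_r(rs, 30)
        assert list(vec) == [pytest.approx(p_from_r(float(r), 30)) for r in rs]

    def test_small_n_rejected(self):
        with pytest.raises(DataError):
            p_from_r(0.5, 2)


class TestCompareGroups:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups([g, g], test="t")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        res = compare_groups([a, b], test="t")
        assert res.p_two_tailed < 1e-4
        assert res.df == (98,)

    def test_anova_equals_t_squared_for_two_groups(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 25)
        t_res = compare_groups([a, b], test="t")
        f_res = compare_groups([a, b], test="anova")
        assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert f_res.p_two_tailed == pytest.approx(t_res.p_two_tailed, rel=1e-9)

    def test_anova_three_groups(self, rng):
        groups = [rng.normal(m, 1, 30) for m in (0, 0, 3)]
        res = compare_groups(groups, test="anova")
        assert res.statistic >= 0
        assert res.df == (2, 87)
        assert res.p_two_tailed < 1e-4

    def test_t_needs_two_groups(self):
        with pytest.raises(ConfigError):
            compare_groups([[1, 2]], test="t")

    def test_tiny_group_rejected(self):
        with pytest.raises(DataError):
            compare_groups([[1.0], [1.0, 2.0]], test="t")


class TestFitGaussian:
    def test_two_points(self):
        fit = fit_gaussian([1.0, 3.0])
        assert fit.mean == pytest.approx(2.0)
        assert fit.sd_ml == pytest.approx(1.0)
        assert fit.sd_sample == pytest.approx(math.sqrt(2.0))

    def test_constant_sample(self):
        assert fit_gaussian([5.0] * 10).sd_ml == 0.0

    def test_truncated_normal_mean_recovered(self, rng):
        draws = rng.normal(50, 45, size=100_000)
        kept = draws[draws > 0]
        # oracle: truncated-normal moment formula
        expected = sps.truncnorm.mean(a=(0 - 50) / 45, b=np.inf, loc=50, scale=45)
        fit = fit_gaussian(kept)
        assert fit.mean == pytest.approx(expected, rel=0.02)

    def test_single_point_rejected(self):
        with pytest.raises(DataError):
            fit_gaussian([1.0])


def _cell(cid, vol=100.0, ri=1.35, count=0, total=0.0):
    return CellStats(
        cell_id=cid,
        cell_volume_um3=vol,
        mean_cell_ri=ri,
        aggregate_count=count,
        total_np_volume_um3=total,
        np_volume_fraction=100 * total / vol,
        mean_aggregate_volume_um3=(total / count) if count else math.nan,
    )


def _agg(aid, cid, vol):
    from holoquant.aggregates import AggregateRecord

    return AggregateRecord(
        id=aid,
        cell_id=cid,
        voxel_count=8,
        volume_um3=vol,
        mean_ri=1.4,
        max_ri=1.41,
        centroid=(0.0, 0.0, 0.0),
    )


class TestBuildReport:
    def test_single_cell_two_aggregates(self):
        cells = [_cell(1, count=2, total=1.0)]
        aggs = [_agg(1, 1, 0.5), _agg(2, 1, 0.5)]
        rep = build_report(cells, aggs).to_dict()
        block = rep["uptake_block"]["aggregate_volume_um3"]
        assert block["mean"] == pytest.approx(0.5)
        assert block["sd"] == pytest.approx(0.0)
        assert rep["uptake_block"]["np_volume_fraction_pct"]["mean"] == (
            pytest.approx(1.0)
        )

    def test_report_is_pure(self):
        cells = [_cell(i, vol=100 + i, count=1, total=0.5) for i in range(1, 5)]
        aggs = [_agg(i, i, 0.5) for i in range(1, 5)]
        assert build_report(cells, aggs).to_dict() == build_report(cells, aggs).to_dict()

    def test_empty_inputs_give_missing_fields(self):
        rep = build_report([], []).to_dict()
        assert rep["uptake_block"]["aggregate_volume_um3"]["mean"] is None
        assert rep["correlations_block"]["cell_volume_vs_np_volume"] is None
        assert rep["histograms_block"]["aggregate_sizes"] is None

    def test_zero_aggregate_cells_excluded_from_size_ri_correlation(self, rng):
        cells = [
            _cell(i, vol=100 + rng.random(), ri=1.34 + 0.01 * rng.random(),
                  count=(1 if i % 2 else 0), total=(0.5 + 0.1 * rng.random() if i % 2 else 0.0))
            for i in range(1, 21)
        ]
        aggs = [_agg(i, i, 0.5) for i in range(1, 21) if i % 2]
        rep = build_report(cells, aggs).to_dict()
        corr = rep["correlations_block"]["mean_aggregate_volume_vs_mean_ri"]
        assert corr is not None
        assert corr["n"] == sum(1 for c in cells if c.aggregate_count > 0)

    def test_correlation_block_matches_direct_pearson(self, rng):
        vols = 100 + 50 * rng.random(30)
        totals = vols * 0.05 + rng.random(30)
        cells = [
            _cell(i + 1, vol=v, count=1, total=t)
            for i, (v, t) in enumerate(zip(vols, totals))
        ]
        aggs = [_agg(i + 1, i + 1, t) for i, t in enumerate(totals)]
        rep = build_report(cells, aggs).to_dict()
        got = rep["correlations_block"]["cell_volume_vs_np_volume"]
        ref = pearson(vols, totals)
        assert got["r"] == pytest.approx(ref.r)
        assert got["p_two_tailed"] == pytest.approx(ref.p_two_tailed)
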