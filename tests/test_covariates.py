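"""Covariate engine vs independent brute-force re-implementations."""

import math

import numpy as np
import pandas as pd
import pytest

from holoreef.covariates import (
    PaleoSeries,
    SaodRecord,
    SeaLevelCurve,
    SstGrid,
    correlation_screen,
    interp_at,
    nearest_valid_cell,
    sample_insolation,
    sample_mean_series,
    sample_sst,
    sea_level_rate,
    segment_grid,
    volcanic_metric,
)
from holoreef.insolation import TSI_REFERENCE, annual_mean_insolation

# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive loops)


def oracle_interp(ages, values, q):
    """Handwritten piecewise-linear with nearest-endpoint extension."""
    out = []
    for x in np.atleast_1d(q):
        if x <= ages[0]:
            out.append(values[0])
        elif x >= ages[-1]:
            out.append(values[-1])
        else:
            for i in range(len(ages) - 1):
                if ages[i] <= x <= ages[i + 1]:
                    f = (x - ages[i]) / (ages[i + 1] - ages[i])
                    out.append(values[i] * (1 - f) + values[i + 1] * f)
                    break
    return np.array(out)


def oracle_grid(t1, t2, step):
    pts = [t1]
    a = t1
    while a + step < t2:
        a += step
        pts.append(a)
    pts.append(t2)
    return np.array(pts)


def oracle_segment_mean(t1, t2, series):
    grid = oracle_grid(t1, t2, series.native_step)
    lo, hi = series.ages[0], series.ages[-1]
    inside = [g for g in grid if lo <= g <= hi]
    pts = inside if inside else list(grid)
    vals = [float(oracle_interp(series.ages, series.values, p)[0]) for p in pts]
    return sum(vals) / len(vals)


def oracle_sea_level_rate(t1, t2, curve):
    years = list(range(math.ceil(t1), math.floor(t2) + 1))
    if len(years) < 2:
        s1 = float(oracle_interp(curve.ages, curve.submergence_m, t1)[0])
        s2 = float(oracle_interp(curve.ages, curve.submergence_m, t2)[0])
        return (s2 - s1) / (t2 - t1) * 1000.0
    s = [float(oracle_interp(curve.ages, curve.submergence_m, y)[0]) for y in years]
    diffs = [s[i + 1] - s[i] for i in range(len(s) - 1)]
    return sum(diffs) / len(diffs) * 1000.0


def oracle_volcanic(t1, t2, lat, saod):
    # annual means by nested loops
    yr = np.floor(saod.ages_monthly).astype(int)
    years = sorted(set(yr))
    annual = {}
    for y in years:
        rows = saod.saod[yr == y]
        band_mean = rows.mean(axis=0)
        # latitude interpolation, clamped
        if lat <= saod.band_lats[0]:
            v = band_mean[0]
        elif lat >= saod.band_lats[-1]:
            v = band_mean[-1]
        else:
            for i in range(len(saod.band_lats) - 1):
                if saod.band_lats[i] <= lat <= saod.band_lats[i + 1]:
                    f = (lat - saod.band_lats[i]) / (saod.band_lats[i + 1] - saod.band_lats[i])
                    v = band_mean[i] * (1 - f) + band_mean[i + 1] * f
                    break
        annual[y] = 25.0 * v
    span = list(range(math.ceil(t1), math.floor(t2) + 1))
    if not span:
        span = [math.floor(t1)]
    ys = sorted(annual)
    f = [float(oracle_interp(np.array(ys, dtype=float),
                             np.array([annual[y] for y in ys]), s)[0]) for s in span]
    if len(f) < 20:
        return sum(f)
    sums = [sum(f[i:i + 20]) for i in range(len(f) - 19)]
    return sum(sums) / len(sums)


# ---------------------------------------------------------------------------


class TestInterp:
    def setup_method(self):
        self.s = PaleoSeries([0.0, 100.0, 300.0], [10.0, 20.0, 5.0], 22.0)

    def test_exact_at_nodes(self):
        np.testing.assert_allclose(interp_at(self.s, [0, 100, 300]), [10, 20, 5])

    def test_linear_midpoint(self):
        assert interp_at(self.s, [50.0])[0] == pytest.approx(15.0)

    def test_nearest_value_beyond_record(self):
        np.testing.assert_allclose(interp_at(self.s, [-50.0, 900.0]), [10.0, 5.0])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            PaleoSeries([], [], 22.0)


class TestSegmentGrid:
    def test_200_year_segment_has_nine_full_steps(self):
        g = segment_grid(4000.0, 4200.0, 22.0)
        assert g[0] == 4000.0 and g[-1] == 4200.0
        full = np.isclose(np.diff(g), 22.0).sum()
        assert full == 9

    def test_sub_step_segment_endpoints_only(self):
        np.testing.assert_allclose(segment_grid(4000.0, 4010.0, 22.0), [4000.0, 4010.0])

    def test_exact_multiple(self):
        np.testing.assert_allclose(segment_grid(0.0, 44.0, 22.0), [0.0, 22.0, 44.0])


class TestSegmentMeans:
    def test_linear_series_gives_midpoint_value(self):
        ages = np.arange(0.0, 2001.0, 8.0)
        s = PaleoSeries(ages, 2.0 * ages + 5.0, 8.0)
        # symmetric grid over [400, 800]: mean of a linear function = midpoint
        assert sample_mean_series(400.0, 800.0, s) == pytest.approx(2.0 * 600.0 + 5.0)

    def test_constant_series(self):
        s = PaleoSeries(np.arange(0.0, 1000.0, 70.0), np.full(15, 7.7), 70.0)
        assert sample_mean_series(123.0, 456.0, s) == pytest.approx(7.7)

    def test_random_cases_match_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            n = int(rng.integers(5, 60))
            ages = np.sort(rng.uniform(0, 10_000, n))
            ages += np.arange(n) * 1e-6
            s = PaleoSeries(ages, rng.normal(size=n), float(rng.uniform(5, 100)))
            t1 = float(rng.uniform(-500, 9_000))
            t2 = t1 + float(rng.uniform(1, 2_000))
            assert sample_mean_series(t1, t2, s) == pytest.approx(
                oracle_segment_mean(t1, t2, s), abs=1e-10)

    def test_insolation_constant_series_reduces_to_annual_mean(self):
        s = PaleoSeries(np.arange(0.0, 9_390.0, 22.0),
                        np.full(427, 0.3), 22.0, name="tsi")
        val, tsi = sample_insolation(2_000.0, 2_500.0, -17.0, s)
        assert tsi == pytest.approx(TSI_REFERENCE + 0.3)
        grid = segment_grid(2_000.0, 2_500.0, 22.0)
        expect = np.mean(annual_mean_insolation(-17.0, grid, TSI_REFERENCE + 0.3))
        assert val == pytest.approx(expect, rel=1e-10)

    def test_insolation_matches_direct_resummation(self):
        rng = np.random.default_rng(2)
        ages = np.arange(0.0, 9_390.0, 22.0)
        s = PaleoSeries(ages, 0.3 * rng.standard_normal(ages.size), 22.0)
        t1, t2 = 3_111.0, 3_700.0
        val, _ = sample_insolation(t1, t2, 9.5, s)
        grid = oracle_grid(t1, t2, 22.0)
        direct = np.mean([
            annual_mean_insolation(9.5, g, TSI_REFERENCE + float(oracle_interp(ages, s.values, g)[0]))
            for g in grid
        ])
        assert val == pytest.approx(direct, abs=1e-10)

    def test_partial_overlap_uses_in_record_points_only(self):
        ages = np.arange(1_000.0, 2_001.0, 22.0)
        s = PaleoSeries(ages, np.linspace(0.0, 1.0, ages.size), 22.0)
        t1, t2 = 500.0, 1_200.0  # T1 outside, T2 inside
        grid = segment_grid(t1, t2, 22.0)
        in_rec = grid[(grid >= 1_000.0) & (grid <= 2_000.0)]
        expect = np.mean([
            annual_mean_insolation(0.0, g, TSI_REFERENCE + float(oracle_interp(ages, s.values, g)[0]))
            for g in in_rec
        ])
        val, _ = sample_insolation(t1, t2, 0.0, s)
        assert val == pytest.approx(expect, abs=1e-10)


class TestSst:
    def make_grid(self, rng=None, constant=None):
        lats = np.arange(-5.0, 6.0, 1.0)
        lons = np.arange(100.0, 111.0, 1.0)
        ages = np.arange(0.0, 2_001.0, 200.0)
        if constant is not None:
            sst = np.full((lats.size, lons.size, ages.size), constant)
        else:
            sst = 25.0 + rng.standard_normal((lats.size, lons.size, ages.size))
        return SstGrid(lats, lons, ages, sst)

    def test_site_on_valid_cell_uses_that_cell(self):
        rng = np.random.default_rng(0)
        grid = self.make_grid(rng)
        val = sample_sst(100.0, 1_900.0, 2.0, 105.0, grid)
        i = list(grid.lats).index(2.0)
        j = list(grid.lons).index(105.0)
        cell = grid.sst[i, j]
        inner = grid.ages[(grid.ages > 100.0) & (grid.ages < 1_900.0)]
        pts = np.concatenate([[100.0], inner, [1_900.0]])
        expect = np.interp(pts, grid.ages, cell).mean()
        assert val == pytest.approx(expect, abs=1e-12)

    def test_missing_cell_falls_to_neighbor_matching_distance_oracle(self):
        rng = np.random.default_rng(1)
        grid = self.make_grid(rng)
        grid.sst[5, 5] = np.nan  # site's own cell is missing
        i, j = nearest_valid_cell(grid, grid.lats[5], grid.lons[5])
        assert np.all(np.isfinite(grid.sst[i, j]))
        # exhaustive oracle: the chosen cell must attain the minimum distance
        best_d = np.inf
        chosen_d = None
        la1, lo1 = np.deg2rad(grid.lats[5]), np.deg2rad(grid.lons[5])
        for a in range(grid.lats.size):
            for b in range(grid.lons.size):
                if not np.all(np.isfinite(grid.sst[a, b])):
                    continue
                la2, lo2 = np.deg2rad(grid.lats[a]), np.deg2rad(grid.lons[b])
                d = np.arccos(np.clip(
                    np.sin(la1) * np.sin(la2) + np.cos(la1) * np.cos(la2) * np.cos(lo2 - lo1),
                    -1, 1))
                best_d = min(best_d, d)
                if (a, b) == (i, j):
                    chosen_d = d
        assert chosen_d == pytest.approx(best_d, abs=1e-12)

    def test_constant_field_returns_constant(self):
        grid = self.make_grid(constant=26.5)
        assert sample_sst(333.0, 388.0, 0.0, 105.0, grid) == pytest.approx(26.5)

    def test_all_missing_grid_rejected(self):
        grid = self.make_grid(constant=26.5)
        grid.sst[:] = np.nan
        with pytest.raises(ValueError):
            sample_sst(100.0, 500.0, 0.0, 105.0, grid)


class TestSeaLevelRate:
    def test_linear_submergence_gives_exact_slope(self):
        ages = np.arange(0.0, 12_001.0, 50.0)
        curve = SeaLevelCurve("r", ages, ages * 0.005)  # +5 m per kyr
        for t1, t2 in [(100.0, 900.0), (2_000.5, 7_321.25), (50.0, 52.0)]:
            assert sea_level_rate(t1, t2, curve) == pytest.approx(5.0, rel=1e-9)

    def test_constant_sea_level_zero_rate(self):
        curve = SeaLevelCurve("r", np.arange(0.0, 1_001.0, 10.0), np.full(101, 2.0))
        assert sea_level_rate(10.0, 900.0, curve) == pytest.approx(0.0, abs=1e-12)

    def test_telescoping_identity_on_integer_endpoints(self):
        # mean of annual differences telescopes to the endpoint slope
        rng = np.random.default_rng(4)
        ages = np.sort(rng.uniform(0, 5_000, 40))
        ages += np.arange(40) * 1e-6
        curve = SeaLevelCurve("r", ages, np.cumsum(rng.uniform(0, 2, 40)))
        t1, t2 = 1_000.0, 3_000.0
        s = PaleoSeries(curve.ages, curve.submergence_m, 1.0)
        expect = (interp_at(s, [t2])[0] - interp_at(s, [t1])[0]) / (t2 - t1) * 1000.0
        assert sea_level_rate(t1, t2, curve) == pytest.approx(expect, abs=1e-9)

    def test_random_cases_match_annual_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            n = int(rng.integers(5, 30))
            ages = np.sort(rng.uniform(0, 10_000, n))
            ages += np.arange(n) * 1e-6
            curve = SeaLevelCurve("r", ages, rng.normal(0, 10, n))
            t1 = float(rng.uniform(0, 8_000))
            t2 = t1 + float(rng.uniform(0.5, 1_500))
            assert sea_level_rate(t1, t2, curve) == pytest.approx(
                oracle_sea_level_rate(t1, t2, curve), abs=1e-9)


class TestVolcanic:
    def constant_record(self, saod_value=0.02, years=200):
        months = np.arange(0.0, years, 1.0 / 12.0) + 1.0 / 24.0
        bands = np.arange(-85.0, 86.0, 10.0)
        return SaodRecord(months, bands, np.full((months.size, bands.size), saod_value))

    def test_constant_record_window_arithmetic(self):
        rec = self.constant_record(0.02)
        # annual forcing 25*0.02 = 0.5; 20-yr window sum 10; mean 10
        assert volcanic_metric(50.0, 150.0, 0.0, rec) == pytest.approx(10.0, rel=1e-9)

    def test_zero_saod_gives_zero(self):
        rec = self.constant_record(0.0)
        assert volcanic_metric(10.0, 90.0, -20.0, rec) == 0.0

    def test_short_segment_single_window(self):
        rec = self.constant_record(0.02)
        # 8 annual values available -> single window summing 8 * 0.5
        assert volcanic_metric(50.2, 58.9, 0.0, rec) == pytest.approx(4.0, rel=1e-9)

    def test_monthly_layout_invariance(self):
        months = np.arange(0.0, 100.0, 1.0 / 12.0) + 1.0 / 24.0
        bands = np.arange(-85.0, 86.0, 10.0)
        rng = np.random.default_rng(0)
        base = np.full((months.size, bands.size), 0.01)
        rec_flat = SaodRecord(months, bands, base)
        # redistribute within each year, keeping annual means fixed
        jitter = rng.uniform(-0.005, 0.005, size=base.shape)
        yr = np.floor(months).astype(int)
        for y in np.unique(yr):
            sel = yr == y
            jitter[sel] -= jitter[sel].mean(axis=0, keepdims=True)
        rec_jit = SaodRecord(months, bands, base + jitter)
        a = volcanic_metric(10.0, 80.0, 5.0, rec_flat)
        b = volcanic_metric(10.0, 80.0, 5.0, rec_jit)
        assert a == pytest.approx(b, abs=1e-9)

    def test_random_eruptions_match_nested_loop_oracle(self):
        rng = np.random.default_rng(12)
        months = np.arange(0.0, 300.0, 1.0 / 12.0) + 1.0 / 24.0
        bands = np.arange(-85.0, 86.0, 10.0)
        saod = np.full((months.size, bands.size), 0.002)
        for _ in range(12):
            i = int(rng.integers(0, months.size - 40))
            saod[i:i + 36] += rng.lognormal(-2.5, 0.8) * np.exp(
                -np.arange(36) / 12.0)[:, None] * np.exp(
                -0.5 * ((bands - rng.uniform(-60, 60)) / 20.0) ** 2)[None, :]
        rec = SaodRecord(months, bands, saod)
        for _ in range(6):
            t1 = float(rng.uniform(0, 200))
            t2 = t1 + float(rng.uniform(5, 90))
            lat = float(rng.uniform(-40, 40))
            assert volcanic_metric(t1, t2, lat, rec) == pytest.approx(
                oracle_volcanic(t1, t2, lat, rec), abs=1e-9)


class TestCorrelationScreen:
    def test_exact_linear_pair_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": rng.normal(size=200)})
        out = correlation_screen(df)
        row = out[(out.var1 == "x") & (out.var2 == "y")].iloc[0]
        assert row.flagged and row.r == pytest.approx(1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=list("abc"))
        out = correlation_screen(df)
        assert not out.flagged.any()
        assert (out.r.abs() < 0.1).all()

    def test_zero_variance_column_undefined_not_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        out = correlation_screen(df)
        assert np.isnan(out.iloc[0].r)
        assert not out.iloc[0].flagged

    def test_latitude_vs_gradient_built_sst_flagged(self):
        # SST built with a latitudinal gradient correlates with |latitude|
        rng = np.random.default_rng(2)
        lat = rng.uniform(-30, 30, 500)
        sst = 29.0 - 5.5 * (np.abs(lat) / 30.0) ** 2 + 0.3 * rng.normal(size=500)
        out = correlation_screen(pd.DataFrame({"abs_latitude": np.abs(lat), "sst": sst}))
        assert out.iloc[0].flagged
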