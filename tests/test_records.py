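"""Core records: uid construction, segment reconstruction, filters, trends."""

import numpy as np
import pandas as pd
import pytest

from holoreef.records import (
    TrendCurve,
    build_core_uid,
    filter_max_age,
    loess,
    percentile_filter,
    read_points,
    reconstruct_segments,
    regional_trend,
)


def make_points(ages, depths, **site):
    base = dict(study="SmithEtAl", core="C-1", lon=150.0, lat=-18.0,
                region="WPacific-S", ocean="Pacific", locality="loc",
                reef_zone="reef crest")
    base.update(site)
    return pd.DataFrame([
        {**base, "age_ybp": a, "depth_mm": d} for a, d in zip(ages, depths)
    ])


class TestCoreUid:
    def test_concatenation_with_reserved_separator(self):
        assert build_core_uid("SmithEtAl", "C-1") == "SmithEtAl::C-1"

    def test_same_core_name_across_studies_distinct(self):
        assert build_core_uid("StudyA", "P8") != build_core_uid("StudyB", "P8")

    def test_no_collision_through_concatenation(self):
        # ("A","B") is valid; ("AB","") is rejected, so no ambiguity arises.
        assert build_core_uid("A", "B") == "A::B"
        with pytest.raises(ValueError):
            build_core_uid("AB", "")
        with pytest.raises(ValueError):
            build_core_uid("  ", "C")


class TestReconstruction:
    def test_two_dates_single_segment(self):
        pts = make_points([4000.0, 5000.0], [1500.0, 2000.0])
        seg = reconstruct_segments(read_points(pts))
        assert len(seg) == 1
        row = seg.iloc[0]
        assert row.rate == pytest.approx(0.5)
        assert row.mean_age == pytest.approx(4500.0)
        assert row.segment_years == pytest.approx(1000.0)

    def test_consecutive_segments_share_boundary_date(self):
        pts = make_points([1000.0, 2000.0, 3500.0], [0.0, 700.0, 1900.0])
        seg = reconstruct_segments(read_points(pts))
        assert len(seg) == 2
        assert seg.iloc[0].T2_age == seg.iloc[1].T1_age == 2000.0

    def test_n_points_yield_n_minus_1_segments(self):
        ages = np.sort(np.random.default_rng(0).uniform(0, 11000, 26))
        depths = np.cumsum(np.random.default_rng(1).uniform(10, 400, 26))
        seg = reconstruct_segments(read_points(make_points(ages, depths)))
        assert len(seg) == 25

    def test_depth_conservation(self):
        rng = np.random.default_rng(3)
        ages = np.sort(rng.uniform(0, 11000, 12))
        depths = np.cumsum(rng.uniform(5, 300, 12))
        seg = reconstruct_segments(read_points(make_points(ages, depths)))
        assert seg.segment_mm.sum() == pytest.approx(depths[-1] - depths[0], abs=1e-9)

    def test_tied_ages_skip_segment_not_core(self, caplog):
        pts = make_points([1000.0, 2000.0, 2000.0, 3000.0],
                          [0.0, 500.0, 600.0, 1100.0])
        with caplog.at_level("WARNING"):
            seg = reconstruct_segments(pts)
        assert len(seg) == 2  # 4 points, 1 tied pair skipped
        assert "tied ages" in caplog.text

    def test_age_depth_inversion_rejected_at_read_time(self):
        pts = make_points([3000.0, 2000.0], [100.0, 500.0])
        with pytest.raises(ValueError, match="inversion"):
            read_points(pts)


class TestAgeFilter:
    def test_boundary_is_inclusive(self):
        pts = make_points([11000.0, 11700.0], [0.0, 500.0])
        seg = reconstruct_segments(read_points(pts))
        assert len(filter_max_age(seg)) == 1

    def test_older_than_boundary_removed(self):
        pts = make_points([11000.0, 11701.0], [0.0, 500.0])
        seg = reconstruct_segments(read_points(pts))
        assert len(filter_max_age(seg)) == 0


def brute_force_percentile(rates, total_mass):
    """Independent oracle: sorted linear-interpolation quantiles, then scan."""
    tail = (1.0 - total_mass) / 2.0
    s = np.sort(rates)
    n = len(s)

    def quantile(q):
        h = q * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    lo, hi = quantile(tail), quantile(1.0 - tail)
    return [i for i, r in enumerate(rates) if lo <= r <= hi]


def samples_from_rates(rates):
    rates = np.asarray(rates, dtype=float)
    return pd.DataFrame({
        "rate": rates,
        "T2_age": np.full(len(rates), 1000.0),
        "region": "WPacific-S",
    })


class TestPercentileFilter:
    def test_integer_rates_match_sort_based_oracle(self):
        rates = np.arange(1.0, 1001.0)
        kept = percentile_filter(samples_from_rates(rates), 0.97)
        expect = brute_force_percentile(rates, 0.97)
        assert list(kept.index) == expect

    def test_identical_rates_nothing_removed(self):
        kept = percentile_filter(samples_from_rates(np.full(50, 3.3)))
        assert len(kept) == 50

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            percentile_filter(samples_from_rates(np.arange(1.0, 101.0)), 1.2)

    def test_stability_under_reapplication(self):
        # A strict central-band filter is not exactly idempotent on
        # continuous rates (the band quantiles of the filtered set move
        # inward), but a second pass must remove no more than the nominal
        # tail mass of the already-filtered set.
        rng = np.random.default_rng(7)
        df = samples_from_rates(rng.lognormal(1.0, 0.8, 500))
        once = percentile_filter(filter_max_age(df))
        twice = percentile_filter(filter_max_age(once))
        assert len(once) - len(twice) <= int(np.ceil(0.03 * len(once))) + 2
        # heavily tied data are exactly idempotent
        tied = samples_from_rates(np.repeat([1.0, 2.0, 3.0], 40))
        pd.testing.assert_frame_equal(percentile_filter(tied),
                                      percentile_filter(percentile_filter(tied)))

    def test_oracle_equivalence_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(10, 120))
            rates = rng.lognormal(rng.normal(), rng.uniform(0.2, 1.5), n)
            mass = rng.uniform(0.8, 0.99)
            kept = percentile_filter(samples_from_rates(rates), mass)
            assert list(kept.index) == brute_force_percentile(rates, mass)


class TestRegionalTrend:
    def region_frame(self, ages, rates):
        return pd.DataFrame({"mean_age": ages, "rate": rates})

    def test_local_linear_exact_on_a_line(self):
        ages = np.linspace(0, 10_000, 60)
        rates = 2.0 + 0.0005 * ages
        curve = regional_trend(self.region_frame(ages, rates))
        np.testing.assert_allclose(curve.mean_rate, 2.0 + 0.0005 * curve.age, atol=1e-8)

    def test_constant_rates_flat_curve(self):
        ages = np.linspace(0, 8_000, 40)
        curve = regional_trend(self.region_frame(ages, np.full(40, 4.2)))
        np.testing.assert_allclose(curve.mean_rate, 4.2, atol=1e-9)

    def test_sparse_region_refused(self):
        with pytest.raises(ValueError, match="samples"):
            regional_trend(self.region_frame(np.arange(5.0), np.arange(5.0)))

    def test_bimodal_region_recovers_both_peaks(self):
        rng = np.random.default_rng(11)
        ages = np.sort(rng.uniform(0, 10_000, 400))
        truth = (3.0 + 2.0 * np.exp(-0.5 * ((ages - 2_500) / 900) ** 2)
                 + 2.0 * np.exp(-0.5 * ((ages - 7_500) / 900) ** 2))
        rates = truth * rng.lognormal(0.0, 0.10, ages.size)
        curve = regional_trend(pd.DataFrame({"mean_age": ages, "rate": rates}),
                               span=0.3, n_grid=101)
        m = curve.mean_rate
        peaks = [i for i in range(1, 100) if m[i] > m[i - 1] and m[i] > m[i + 1]]
        top2 = sorted(sorted(peaks, key=lambda i: -m[i])[:2])
        grid_step = curve.age[1] - curve.age[0]
        assert abs(curve.age[top2[0]] - 2_500) <= 5 * grid_step
        assert abs(curve.age[top2[1]] - 7_500) <= 5 * grid_step

    def test_band_contains_mean_and_is_ordered(self):
        rng = np.random.default_rng(5)
        ages = np.sort(rng.uniform(0, 9_000, 120))
        rates = rng.lognormal(1.2, 0.4, 120)
        curve = regional_trend(pd.DataFrame({"mean_age": ages, "rate": rates}))
        assert isinstance(curve, TrendCurve)
        assert np.all(curve.lower <= curve.mean_rate)
        assert np.all(curve.mean_rate <= curve.upper)
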