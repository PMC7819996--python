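"""Climatology, anomalies, 13-term smoothing and Spearman trend tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_record
from echolayers.synthetic import EnvSeriesConfig, generate_env_series
from echolayers.trends import (
    EnvSeries,
    acoustic_annual_series,
    anomalies,
    monthly_climatology,
    smooth_13term,
    spearman_trend,
)


def make_series(values, start="1995-01-01", variable="SST"):
    values = np.asarray(values, dtype=float)
    times = pd.date_range(start, periods=len(values), freq="MS")
    return EnvSeries(variable=variable, times=times, values=values)


class TestClimatology:
    def test_constant_series(self):
        clim = monthly_climatology(make_series(np.full(36, 4.2)))
        np.testing.assert_allclose(clim, 4.2)

    def test_pure_sinusoid_reproduced(self):
        m = np.arange(48)
        values = 3.0 * np.sin(2 * np.pi * m / 12.0)
        clim = monthly_climatology(make_series(values))
        np.testing.assert_allclose(
            clim, 3.0 * np.sin(2 * np.pi * np.arange(12) / 12.0), atol=1e-9
        )

    def test_two_year_mean(self):
        values = np.zeros(24)
        values[0], values[12] = 1.0, 3.0
        clim = monthly_climatology(make_series(values))
        assert clim[0] == pytest.approx(2.0)

    def test_month_missing_everywhere_is_error(self):
        values = np.full(24, 1.0)
        values[[0, 12]] = np.nan
        with pytest.raises(ValueError, match="January"):
            monthly_climatology(make_series(values))


class TestAnomalies:
    def test_climatology_tiling_gives_zero(self):
        m = np.arange(60)
        values = 5.0 + 2.0 * np.sin(2 * np.pi * m / 12.0)
        s = make_series(values)
        anom = anomalies(s, monthly_climatology(s))
        np.testing.assert_allclose(anom.values, 0.0, atol=1e-9)
        # per calendar month the anomalies of a complete series sum to zero
        frame = pd.DataFrame({"m": s.times.month, "a": anom.values})
        np.testing.assert_allclose(frame.groupby("m")["a"].sum(), 0.0, atol=1e-9)

    def test_constant_offset_preserved(self):
        s = make_series(np.full(36, 7.0))
        anom = anomalies(make_series(np.full(36, 8.0)), monthly_climatology(s))
        np.testing.assert_allclose(anom.values, 1.0)

    def test_linear_trend_survives_deseasonalisation(self):
        slope = 0.01  # per month
        m = np.arange(240, dtype=float)
        values = 20.0 + 3.0 * np.sin(2 * np.pi * m / 12.0) + slope * m
        s = make_series(values)
        anom = anomalies(s, monthly_climatology(s))
        fit = np.polyfit(m, anom.values, 1)
        assert fit[0] == pytest.approx(slope, rel=0.05)

    def test_missing_propagates(self):
        values = np.full(36, 2.0)
        values[5] = np.nan
        s = make_series(values)
        clim = np.full(12, 2.0)
        anom = anomalies(s, clim)
        assert np.isnan(anom.values[5]) and np.isfinite(anom.values[4])


class TestSmooth13Term:
    def test_constant_unchanged_where_defined(self):
        out = smooth_13term(np.full(30, 2.5))
        assert np.isnan(out[:6]).all() and np.isnan(out[-6:]).all()
        np.testing.assert_allclose(out[6:-6], 2.5)

    def test_annual_cycle_annihilated(self):
        m = np.arange(60)
        out = smooth_13term(np.sin(2 * np.pi * m / 12.0))
        np.testing.assert_allclose(out[6:-6], 0.0, atol=1e-9)

    def test_linearity_preserved(self):
        m = np.arange(40, dtype=float)
        out = smooth_13term(1.5 + 0.25 * m)
        np.testing.assert_allclose(out[6:-6], 1.5 + 0.25 * m[6:-6], atol=1e-9)

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            smooth_13term(np.arange(12))


class TestSpearmanTrend:
    def test_perfect_monotone(self):
        up = spearman_trend([1.0, 2.0, 5.0, 9.0, 12.0], [1, 2, 3, 4, 5])
        assert up.rho == pytest.approx(1.0)
        down = spearman_trend([5.0, 4.0, 3.0, 2.0, 1.0], [1, 2, 3, 4, 5])
        assert down.rho == pytest.approx(-1.0)

    def test_constant_series_degenerate(self):
        res = spearman_trend([2.0] * 6, list(range(6)))
        assert res.degenerate and res.rho == 0.0 and res.p_value == 1.0

    def test_exact_small_sample_matches_enumeration(self):
        values = [3.0, 1.0, 4.0, 1.0, 5.0]
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = spearman_trend(values, times)
        rho_ref, p_ref = oracles.brute_force_spearman(values, times)
        assert res.rho == pytest.approx(rho_ref, rel=1e-12)
        assert res.p_value == pytest.approx(float(p_ref), rel=1e-12)
        # p is an exact rational with denominator dividing 5!
        assert math.factorial(5) % p_ref.denominator == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=7)
        res = spearman_trend(values, np.arange(7.0))
        rho_ref, p_ref = oracles.brute_force_spearman(values, np.arange(7.0))
        assert res.rho == pytest.approx(rho_ref, rel=1e-12)
        assert res.p_value == pytest.approx(float(p_ref), rel=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=12)
        t = np.arange(12.0)
        a = spearman_trend(values, t)
        b = spearman_trend(np.exp(values), t)  # strictly monotone map
        assert a.rho == pytest.approx(b.rho, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_large_n_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        values = rng.normal(size=40) + 0.05 * np.arange(40)
        res = spearman_trend(values, np.arange(40.0))
        ref = stats.spearmanr(np.arange(40.0), values)
        assert res.rho == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            spearman_trend([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestAcousticAnnualSeries:
    def _survey(self, yearly_nasc):
        recs = []
        for year, values in yearly_nasc.items():
            for v in values:
                recs.append(
                    make_record(time=f"{year}-11-15 12:00:00", nasc={"PG": v})
                )
        return recs

    def test_equal_years_zero_anomaly(self):
        recs = self._survey({1995: [2.0, 4.0], 1996: [3.0, 3.0], 1997: [1.0, 5.0]})
        out = acoustic_annual_series(recs, "PG")
        np.testing.assert_allclose(out["mean_nasc"], 3.0)
        np.testing.assert_allclose(out["anomaly"], 0.0)

    def test_one_year_doubled(self):
        """k years at m, one at 2m: that year's anomaly is m*(k-1)/k... by direct means."""
        m, k = 4.0, 4  # three baseline years + the doubled one
        recs = self._survey({1995: [m], 1996: [m], 1997: [m], 1998: [2 * m]})
        out = acoustic_annual_series(recs, "PG")
        grand = (3 * m + 2 * m) / k
        assert out.loc[out.year == 1998, "anomaly"].item() == pytest.approx(
            2 * m - grand
        )
        assert 2 * m - grand == pytest.approx(m * (k - 1) / k)

    def test_env_series_generator_round_trip(self):
        """Generated series feeds the climatology/anomaly chain coherently."""
        s = generate_env_series(
            EnvSeriesConfig("SST", n_years=10, mean_level=22.0,
                            seasonal_amplitude=3.0, trend_per_decade=0.0,
                            noise_sd=0.0, seed=1)
        )
        anom = anomalies(s, monthly_climatology(s))
        np.testing.assert_allclose(anom.values, 0.0, atol=1e-9)
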