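import numpy as np
import pandas as pd
import pytest

from npsi.aggregate import (METRIC_COLUMNS, annual_means, monthly_means,
                            overall_means, sample_metrics, season_of_month,
                            seasonal_min_si, site_summary)


@pytest.mark.parametrize("month, season", [
    (3, "spring"), (5, "spring"), (6, "summer"), (8, "summer"),
    (9, "autumn"), (11, "autumn"), (12, "winter"), (1, "winter"), (2, "winter"),
])
def test_season_mapping(month, season):
    assert season_of_month(month) == season


def _metric_df(rows):
    df = pd.DataFrame(rows)
    for col in METRIC_COLUMNS:
        if col not in df:
            df[col] = 1.0
    return df


class TestAggregationLadder:
    def test_overall_is_mean_of_annual_means_not_pooled(self):
        # year A: 12 samples at 10; year B: 6 samples at 20 -> overall 15
        rows = ([{"site_id": "a", "year": 2020, "month": 1 + i % 12, "n_pct": 10.0}
                 for i in range(12)]
                + [{"site_id": "a", "year": 2021, "month": 1 + i, "n_pct": 20.0}
                   for i in range(6)])
        overall = overall_means(_metric_df(rows))
        assert overall.loc[0, "n_pct"] == 15.0  # pooled mean would be 13.33

    def test_single_year_collapses_to_plain_mean(self):
        rows = [{"site_id": "a", "year": 2020, "month": m, "n_pct": float(m)}
                for m in range(1, 13)]
        overall = overall_means(_metric_df(rows))
        assert overall.loc[0, "n_pct"] == pytest.approx(np.mean(range(1, 13)))

    def test_constant_metric_survives_every_level(self):
        rows = [{"site_id": "a", "year": y, "month": m, "n_pct": 7.5}
                for y in (2020, 2021) for m in range(1, 13)]
        df = _metric_df(rows)
        assert (annual_means(df)["n_pct"] == 7.5).all()
        assert (monthly_means(df)["n_pct"] == 7.5).all()
        assert (overall_means(df)["n_pct"] == 7.5).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rows = [{"site_id": f"s{i % 3}", "year": 2017 + i % 4, "month": 1 + i % 12,
                 "n_pct": float(rng.uniform(0, 100))} for i in range(200)]
        df = _metric_df(rows)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = overall_means(df).sort_values("site_id").reset_index(drop=True)
        b = overall_means(shuffled).sort_values("site_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_balanced_design_equals_pooled_mean(self):
        rng = np.random.default_rng(7)
        rows = [{"site_id": "a", "year": y, "month": m, "n_pct": float(rng.uniform(0, 100))}
                for y in range(2017, 2021) for m in range(1, 13)]
        df = _metric_df(rows)
        assert overall_means(df).loc[0, "n_pct"] == pytest.approx(df["n_pct"].mean())

    def test_monthly_within_year_first_vs_pooled(self):
        # month 1 sampled once in 2020 (v=10) and twice in 2021 (v=20, 30)
        rows = [
            {"site_id": "a", "year": 2020, "month": 1, "n_pct": 10.0},
            {"site_id": "a", "year": 2021, "month": 1, "n_pct": 20.0},
            {"site_id": "a", "year": 2021, "month": 1, "n_pct": 30.0},
        ]
        df = _metric_df(rows)
        assert monthly_means(df).loc[0, "n_pct"] == pytest.approx(17.5)  # (10 + 25)/2
        assert monthly_means(df, within_year_first=False).loc[0, "n_pct"] == pytest.approx(20.0)

    def test_overall_lies_within_annual_range(self):
        rng = np.random.default_rng(9)
        rows = [{"site_id": "a", "year": y, "month": m, "n_pct": float(rng.uniform(0, 100))}
                for y in range(2017, 2025) for m in range(1, 13)]
        df = _metric_df(rows)
        ann = annual_means(df)["n_pct"]
        val = overall_means(df).loc[0, "n_pct"]
        assert ann.min() <= val <= ann.max()


class TestSeasonalMinSi:
    def _monthly(self, values):
        return pd.DataFrame({"site_id": "a", "month": range(1, 13), "si_pct": values})

    def test_minimum_month_and_season(self):
        values = [50.0] * 12
        values[4] = 18.0  # May
        r = seasonal_min_si(self._monthly(values), "a")
        assert (r.min_si_pct, r.min_si_month, r.min_si_season) == (18.0, 5, "spring")
        assert r.depleted

    def test_constant_series_ties_to_january(self):
        r = seasonal_min_si(self._monthly([45.0] * 12), "a")
        assert r.min_si_month == 1 and not r.depleted

    def test_december_minimum_is_winter(self):
        values = [50.0] * 12
        values[11] = 30.0
        assert seasonal_min_si(self._monthly(values), "a").min_si_season == "winter"

    def test_missing_months_are_skipped(self):
        df = self._monthly([50.0] * 12)
        df.loc[df["month"] == 5, "si_pct"] = np.nan
        df.loc[df["month"] == 7, "si_pct"] = 25.0
        assert seasonal_min_si(df, "a").min_si_month == 7

    def test_no_monthly_values_rejected(self):
        with pytest.raises(ValueError):
            seasonal_min_si(self._monthly([np.nan] * 12), "a")


class TestSiteSummary:
    def test_one_row_per_site_and_zone_consistency(self, small_network):
        from npsi.ingest import harmonize
        samples, sites, truth = small_network
        metrics = sample_metrics(harmonize(samples))
        summary = site_summary(metrics, sites.set_index("site_id", drop=False))
        assert sorted(summary["site_id"]) == sorted(truth["site_id"])
        assert summary["site_id"].is_unique
        # monthly extremes bracket the overall exceedance
        assert (summary["d_din_monthly_min"] <= summary["d_din"] + 1e-9).all()
        assert (summary["d_din"] <= summary["d_din_monthly_max"] + 1e-9).all()
        assert summary["icep"].notna().all()  # runoff present in site table
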