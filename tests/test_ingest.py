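import numpy as np
import pandas as pd
import pytest

from npsi.ingest import (IngestConfig, compute_din, harmonize, qc_retain,
                         read_samples)


class TestComputeDin:
    @pytest.mark.parametrize("kwargs, expected", [
        (dict(no3_no2=400.0, nh4=50.0), 450.0),
        (dict(no3_no2=0.0, nh4=0.0), 0.0),
        (dict(no3_no2=583.0, nh4=None), 583.0),   # single-species programmes
        (dict(no3=300.0, nh4=20.0), 320.0),
        (dict(no3_no2=np.nan, nh4=25.0), 25.0),
    ])
    def test_sums_available_species(self, kwargs, expected):
        assert compute_din(**kwargs) == expected

    def test_all_missing_is_unusable(self):
        assert compute_din() is None
        assert compute_din(no3_no2=np.nan, nh4=np.nan) is None

    def test_order_invariant(self):
        assert compute_din(no3_no2=1.0, nh4=2.0) == compute_din(nh4=2.0, no3_no2=1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_din(no3_no2=-1.0)


def _raw(rows):
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestHarmonize:
    def test_din_and_sio2_conversion(self):
        df = _raw([{"site_id": "a", "date": "2020-06-01",
                    "no3_no2": 400.0, "nh4": 50.0, "totp": 20.0, "sio2": 60.08}])
        out = harmonize(df, IngestConfig(window_start="2020-01-01", window_end="2020-12-31"))
        assert out.loc[0, "din"] == 450.0
        assert out.loc[0, "si"] == pytest.approx(28.08)

    def test_si_preferred_over_sio2(self):
        df = _raw([{"site_id": "a", "date": "2020-06-01", "no3_no2": 1.0,
                    "totp": 1.0, "si": 100.0, "sio2": 60.08}])
        out = harmonize(df, IngestConfig(window_start="2020-01-01", window_end="2020-12-31"))
        assert out.loc[0, "si"] == 100.0

    def test_duplicate_site_dates_averaged(self):
        df = _raw([
            {"site_id": "a", "date": "2020-06-01", "no3_no2": 100.0, "totp": 10.0, "si": 1000.0},
            {"site_id": "a", "date": "2020-06-01", "no3_no2": 300.0, "totp": 30.0, "si": 3000.0},
        ])
        out = harmonize(df, IngestConfig(window_start="2020-01-01", window_end="2020-12-31"))
        assert len(out) == 1
        assert out.loc[0, "totp"] == 20.0

    def test_window_cut(self):
        df = _raw([
            {"site_id": "a", "date": "2016-12-31", "no3_no2": 1.0, "totp": 1.0, "si": 1.0},
            {"site_id": "a", "date": "2017-01-01", "no3_no2": 1.0, "totp": 1.0, "si": 1.0},
        ])
        out = harmonize(df)
        assert list(out["date"]) == [pd.Timestamp("2017-01-01")]

    def test_below_detection_policies(self):
        df = _raw([{"site_id": "a", "date": "2020-06-01", "no3_no2": 1.0,
                    "totp": 3.0, "detection_limit_totp": 4.0, "si": 1.0}])
        half = harmonize(df.copy(), IngestConfig(window_start="2020-01-01",
                                                 window_end="2020-12-31"))
        raw = harmonize(df.copy(), IngestConfig(window_start="2020-01-01",
                                                window_end="2020-12-31",
                                                bdl_policy="as_reported"))
        assert half.loc[0, "totp"] == 2.0  # half the reported limit
        assert raw.loc[0, "totp"] == 3.0

    def test_depth_filter(self):
        df = _raw([
            {"site_id": "a", "date": "2020-06-01", "depth": 0.5,
             "no3_no2": 1.0, "totp": 1.0, "si": 1.0},
            {"site_id": "a", "date": "2020-07-01", "depth": 5.0,
             "no3_no2": 1.0, "totp": 1.0, "si": 1.0},
        ])
        out = harmonize(df, IngestConfig(window_start="2020-01-01", window_end="2020-12-31"))
        assert len(out) == 1

    def test_negative_concentration_rejected(self):
        df = _raw([{"site_id": "a", "date": "2020-06-01",
                    "no3_no2": -5.0, "totp": 1.0, "si": 1.0}])
        with pytest.raises(ValueError, match="negative"):
            harmonize(df, IngestConfig(window_start="2020-01-01", window_end="2020-12-31"))


def _site_rows(site, obs_per_year, years=range(2017, 2025)):
    rows = []
    for year in years:
        n = obs_per_year(year) if callable(obs_per_year) else obs_per_year
        for i in range(n):
            rows.append({"site_id": site, "date": pd.Timestamp(year=year, month=1 + i % 12, day=5),
                         "din": 100.0, "totp": 10.0, "si": 1000.0,
                         "year": year, "month": 1 + i % 12})
    return rows


class TestQcRetain:
    def test_monthly_site_retained(self):
        df = pd.DataFrame(_site_rows("a", 12))
        out, dropped = qc_retain(df)
        assert set(out["site_id"]) == {"a"} and not dropped

    def test_one_sparse_year_drops_site(self):
        df = pd.DataFrame(_site_rows("a", lambda y: 5 if y == 2019 else 12))
        out, dropped = qc_retain(df)
        assert out.empty and "2019" in dropped["a"]

    def test_boundary_six_obs_is_retained(self):
        df = pd.DataFrame(_site_rows("a", 6))
        out, _ = qc_retain(df)
        assert not out.empty

    def test_unusable_samples_do_not_count(self):
        rows = _site_rows("a", 6)
        for r in rows:
            r["si"] = np.nan
        out, dropped = qc_retain(pd.DataFrame(rows))
        assert out.empty and "a" in dropped

    def test_idempotent(self):
        df = pd.DataFrame(_site_rows("a", 12) + _site_rows("b", 3))
        once, _ = qc_retain(df)
        twice, _ = qc_retain(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        out, dropped = qc_retain(pd.DataFrame(columns=["site_id", "year", "din", "totp", "si"]))
        assert out.empty and dropped == {}


def test_read_samples_schema_errors(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("site_id,date,totp\na,2020-01-01,3\n")
    with pytest.raises(ValueError, match="nitrogen"):
        read_samples(p)
    p.write_text("site_id,date,no3_no2,si\na,2020-01-01,3,1\n")
    with pytest.raises(ValueError, match="missing required"):
        read_samples(p)
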