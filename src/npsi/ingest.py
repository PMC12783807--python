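"""Reading and harmonising raw river-mouth monitoring records.

Raw CSVs carry one row per water sample with whatever nutrient columns a
national programme reports: nitrate+nitrite (``no3_no2``) or plain nitrate
(``no3``), ammonium (``nh4``), total P (``totp``), and silica as either
elemental Si (``si``) or SiO₂ (``sio2``), all in µg l⁻¹ of the element
(µg SiO₂ l⁻¹ for ``sio2``). Harmonisation produces uniform ``din``,
``totp`` and ``si`` columns:

* DIN is the sum of the available inorganic-N species — nitrate(+nitrite)
  plus ammonium where both exist, a single species where only one is
  reported (monitoring programmes differ in which fractions they measure);
  DIN is missing only when every species is missing.
* Si comes from the ``si`` column where present, otherwise from SiO₂ by
  the molar-mass ratio 28.08/60.08.
* Below-detection values (rows with a non-missing
  ``detection_limit_<analyte>`` entry) are replaced by half the limit
  under the default policy, or kept as reported.

Quality control retains a site only if every calendar year of the study
window (2017–2024 by default) has at least ``min_obs_per_year`` samples
(default 6) with usable DIN, TotP and Si jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import si_from_sio2

__all__ = [
    "IngestConfig",
    "read_samples",
    "read_sites",
    "compute_din",
    "harmonize",
    "qc_retain",
]

log = logging.getLogger(__name__)

_N_SPECIES = ("no3_no2", "no3", "nh4")
_BDL_ANALYTES = ("no3_no2", "no3", "nh4", "totp", "si", "sio2")


@dataclass(frozen=True)
class IngestConfig:
    """Study window, QC rule and below-detection policy."""

    window_start: str = "2017-01-01"
    window_end: str = "2024-12-31"
    min_obs_per_year: int = 6
    bdl_policy: str = "half_limit"  # or "as_reported"
    max_depth_m: float = 1.0

    def __post_init__(self):
        if self.bdl_policy not in ("half_limit", "as_reported"):
            raise ValueError(f"unknown bdl policy {self.bdl_policy!r}")
        if self.min_obs_per_year < 1:
            raise ValueError("min_obs_per_year must be >= 1")


def read_samples(path) -> pd.DataFrame:
    """Read a raw sample CSV (ISO-8601 dates) into a DataFrame."""
    df = pd.read_csv(path)
    missing = {"site_id", "date", "totp"} - set(df.columns)
    if missing:
        raise ValueError(f"sample CSV is missing required columns: {sorted(missing)}")
    if not any(c in df.columns for c in _N_SPECIES):
        raise ValueError("sample CSV has no nitrogen column (no3_no2, no3 or nh4)")
    if not any(c in df.columns for c in ("si", "sio2")):
        raise ValueError("sample CSV has no silica column (si or sio2)")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_sites(path) -> pd.DataFrame:
    """Read site metadata (country, coordinates, catchment area, runoff)."""
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise ValueError("site CSV must have a site_id column")
    if "area_km2" in df.columns and np.any(df["area_km2"].dropna() <= 0):
        raise ValueError("catchment area must be positive where present")
    return df.set_index("site_id", drop=False)


def compute_din(no3_no2=None, nh4=None, no3=None):
    """DIN (µg N l⁻¹) as the sum of available inorganic-N species.

    ``None``/NaN species are skipped; all species missing returns None
    (record unusable for N metrics). Order of species never matters.
    """
    parts = [v for v in (no3_no2, no3, nh4) if v is not None and not pd.isna(v)]
    if not parts:
        return None
    if any(v < 0 for v in parts):
        raise ValueError("nitrogen concentrations must be non-negative")
    return float(sum(parts))


def _apply_bdl(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    if policy == "as_reported":
        return df
    for analyte in _BDL_ANALYTES:
        lim_col = f"detection_limit_{analyte}"
        if analyte in df.columns and lim_col in df.columns:
            below = df[lim_col].notna()
            df.loc[below, analyte] = df.loc[below, lim_col] / 2.0
    return df


def harmonize(df: pd.DataFrame, config: IngestConfig = IngestConfig()) -> pd.DataFrame:
    """Clean raw samples into uniform per-sample records.

    Steps, in order: depth filter (when a ``depth`` column exists),
    below-detection substitution, DIN summation, SiO₂→Si conversion,
    averaging of duplicate site-date records, and the study-window cut.
    Returns a DataFrame with ``site_id, date, year, month, din, totp, si``.
    """
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "depth" in df.columns:
        df = df[df["depth"].isna() | (df["depth"] < config.max_depth_m)]
    df = _apply_bdl(df, config.bdl_policy)

    for col in _N_SPECIES + ("totp", "si", "sio2"):
        if col in df.columns and np.any(df[col].dropna() < 0):
            raise ValueError(f"negative concentrations in column {col!r}")

    n_cols = [c for c in _N_SPECIES if c in df.columns]
    df["din"] = df[n_cols].sum(axis=1, min_count=1)

    if "si" in df.columns and "sio2" in df.columns:
        df["si"] = df["si"].where(df["si"].notna(), si_from_sio2(df["sio2"]))
    elif "sio2" in df.columns:
        df["si"] = si_from_sio2(df["sio2"])

    keep = ["site_id", "date", "din", "totp", "si"]
    out = df[keep].groupby(["site_id", "date"], as_index=False).mean()

    start, end = pd.Timestamp(config.window_start), pd.Timestamp(config.window_end)
    out = out[(out["date"] >= start) & (out["date"] <= end)].reset_index(drop=True)
    out["year"] = out["date"].dt.year
    out["month"] = out["date"].dt.month
    return out


def qc_retain(df: pd.DataFrame, config: IngestConfig = IngestConfig()):
    """Apply the minimum-observations-per-year retention rule.

    A site is retained iff *every* calendar year of the window has at
    least ``min_obs_per_year`` samples with DIN, TotP and Si all usable.
    Returns ``(retained_df, dropped)`` where ``dropped`` maps site_id to
    a human-readable reason. Idempotent on its own output.
    """
    if df.empty:
        log.warning("qc_retain: empty input, nothing retained")
        return df.copy(), {}
    start_year = pd.Timestamp(config.window_start).year
    end_year = pd.Timestamp(config.window_end).year
    years = range(start_year, end_year + 1)

    usable = df[df[["din", "totp", "si"]].notna().all(axis=1)]
    counts = usable.groupby(["site_id", "year"]).size()

    retained, dropped = [], {}
    for site in df["site_id"].unique():
        bad = [y for y in years if counts.get((site, y), 0) < config.min_obs_per_year]
        if bad:
            dropped[site] = (
                f"fewer than {config.min_obs_per_year} usable observations in "
                f"year(s) {', '.join(map(str, bad))}"
            )
        else:
            retained.append(site)
    out = df[df["site_id"].isin(retained)].reset_index(drop=True)
    return out, dropped
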