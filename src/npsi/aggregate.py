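"""Per-sample metrics and the sample → monthly/annual → overall aggregation ladder.

All stoichiometric quantities (Redfield percentages, critical
concentrations, exceedance ratios) are computed for each sample
individually and only then averaged: first within a year (or a
year-month), then across years, then overall. The overall value is the
mean of annual means — not the pooled sample mean — so years with uneven
sampling effort carry equal weight. Depletion zones and TSI are assigned
at the aggregated level from the aggregated percentages/concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import icep as icep_mod
from . import stoichiometry, trophic
from .units import CONSTANTS, ElementConstants, to_molar

__all__ = [
    "SEASON_OF_MONTH",
    "season_of_month",
    "sample_metrics",
    "annual_means",
    "monthly_means",
    "overall_means",
    "seasonal_min_si",
    "site_summary",
    "METRIC_COLUMNS",
]

SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: Per-sample metric columns that run up the aggregation ladder.
METRIC_COLUMNS = [
    "din_umol", "totp_umol", "si_umol",
    "n_pct", "p_pct", "si_pct",
    "din_0", "totp_0", "d_din", "d_totp",
]


def season_of_month(month: int) -> str:
    """Meteorological season: Mar–May spring, Jun–Aug summer, Sep–Nov autumn, Dec–Feb winter."""
    return SEASON_OF_MONTH[int(month)]


def sample_metrics(samples: pd.DataFrame,
                   constants: ElementConstants = CONSTANTS) -> pd.DataFrame:
    """Attach per-sample stoichiometric metrics to harmonised samples.

    Expects µg l⁻¹ columns ``din, totp, si`` plus ``site_id, year, month``;
    adds molar concentrations, ternary percentages, critical
    concentrations and exceedance ratios (each sample's own Si sets its
    critical values).
    """
    out = samples.copy()
    out["din_umol"] = to_molar(out["din"], "N", constants)
    out["totp_umol"] = to_molar(out["totp"], "P", constants)
    out["si_umol"] = to_molar(out["si"], "Si", constants)
    n_pct, p_pct, si_pct = stoichiometry.redfield_percentages(
        out["din_umol"].to_numpy(), out["totp_umol"].to_numpy(),
        out["si_umol"].to_numpy(), constants)
    out["n_pct"], out["p_pct"], out["si_pct"] = n_pct, p_pct, si_pct
    din_0, totp_0 = icep_mod.critical_concentrations(out["si"].to_numpy(), constants)
    out["din_0"], out["totp_0"] = din_0, totp_0
    out["d_din"] = icep_mod.exceedance(out["din"].to_numpy(), din_0)
    out["d_totp"] = icep_mod.exceedance(out["totp"].to_numpy(), totp_0)
    return out


def annual_means(metrics: pd.DataFrame, columns=METRIC_COLUMNS) -> pd.DataFrame:
    """Mean of each metric over the samples of each site-year."""
    return metrics.groupby(["site_id", "year"], as_index=False)[list(columns)].mean()


def monthly_means(metrics: pd.DataFrame, columns=METRIC_COLUMNS,
                  within_year_first: bool = True) -> pd.DataFrame:
    """One value per site per calendar month.

    Default: average within each year-month, then across years, so every
    sampled year contributes equally to its calendar month. Setting
    ``within_year_first=False`` pools all samples of a calendar month.
    """
    if within_year_first:
        per_ym = metrics.groupby(["site_id", "year", "month"], as_index=False)[list(columns)].mean()
        return per_ym.groupby(["site_id", "month"], as_index=False)[list(columns)].mean()
    return metrics.groupby(["site_id", "month"], as_index=False)[list(columns)].mean()


def overall_means(metrics: pd.DataFrame, columns=METRIC_COLUMNS) -> pd.DataFrame:
    """Overall site value: the mean of the annual means."""
    ann = annual_means(metrics, columns)
    return ann.groupby("site_id", as_index=False)[list(columns)].mean()


@dataclass(frozen=True)
class MinSiResult:
    min_si_pct: float
    min_si_month: int
    min_si_season: str
    depleted: bool


def seasonal_min_si(monthly: pd.DataFrame, site_id,
                    threshold: float = stoichiometry.DEPLETION_THRESHOLD) -> MinSiResult:
    """Minimum monthly Redfield Si percentage of a site, with month and season.

    Ties go to the earliest calendar month. A minimum below the depletion
    threshold flags potential seasonal Si depletion even where the overall
    average is balanced.
    """
    rows = monthly.loc[(monthly["site_id"] == site_id) & monthly["si_pct"].notna()]
    if rows.empty:
        raise ValueError(f"no monthly Si percentages available for site {site_id!r}")
    rows = rows.sort_values("month")
    idx = rows["si_pct"].to_numpy().argmin()  # argmin takes the first on ties
    month = int(rows["month"].iloc[idx])
    value = float(rows["si_pct"].iloc[idx])
    return MinSiResult(value, month, season_of_month(month), value < threshold)


def site_summary(metrics: pd.DataFrame, sites: pd.DataFrame | None = None,
                 threshold: float = stoichiometry.DEPLETION_THRESHOLD,
                 constants: ElementConstants = CONSTANTS) -> pd.DataFrame:
    """One row per site: overall composition, zone, TSI, critical metrics.

    ``sites`` may carry a ``runoff`` column (l km⁻² d⁻¹) enabling ICEP;
    without it, only concentration-based metrics are reported (one of the
    practical advantages of the critical-concentration formulation).
    """
    overall = overall_means(metrics).set_index("site_id")
    monthly = monthly_means(metrics)

    rows = []
    for site, m in overall.iterrows():
        zone = stoichiometry.classify_zone(m["n_pct"], m["p_pct"], m["si_pct"], threshold)
        assessment = trophic.select_basis_and_classify(m["din_umol"], m["totp_umol"], constants)
        min_si = seasonal_min_si(monthly, site, threshold)

        site_monthly = monthly[monthly["site_id"] == site]
        runoff = None
        if sites is not None and "runoff" in sites.columns and site in sites.index:
            r = sites.loc[site, "runoff"]
            runoff = float(r) if pd.notna(r) else None
        crit = icep_mod.assess_critical(
            din=m["din_umol"] * constants.mass_n,
            totp=m["totp_umol"] * constants.mass_p,
            si=m["si_umol"] * constants.mass_si,
            runoff_l_km2_d=runoff, constants=constants)

        rows.append({
            "site_id": site,
            "din_umol": m["din_umol"], "totp_umol": m["totp_umol"], "si_umol": m["si_umol"],
            "n_pct": m["n_pct"], "p_pct": m["p_pct"], "si_pct": m["si_pct"],
            "zone": zone.value,
            "np_ratio": assessment.np_molar_ratio,
            "basis": assessment.basis,
            "tsi": assessment.tsi,
            "tsi_class": assessment.tsi_class.value,
            "din_0": m["din_0"], "totp_0": m["totp_0"],
            "d_din": m["d_din"], "d_totp": m["d_totp"],
            "d_din_monthly_max": site_monthly["d_din"].max(),
            "d_din_monthly_min": site_monthly["d_din"].min(),
            "d_totp_monthly_max": site_monthly["d_totp"].max(),
            "d_totp_monthly_min": site_monthly["d_totp"].min(),
            "min_si_pct": min_si.min_si_pct,
            "min_si_month": min_si.min_si_month,
            "min_si_season": min_si.min_si_season,
            "seasonal_si_depleted": min_si.depleted,
            "icep": crit.icep if crit.icep is not None else np.nan,
            "icep_basis": crit.icep_basis,
        })
    return pd.DataFrame(rows)
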