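"""Synthetic Nordic-style river-mouth monitoring data.

The generator emulates the statistical structure of monthly north-Nordic
monitoring series so the whole pipeline is testable without any download:

* a north–south gradient in DIN and total P (log-linear in latitude,
  southern sites the richest);
* latitude-independent Si with lognormal between-site spread;
* a seasonal Si drawdown — a multiplicative sinusoid with its trough in
  the diatom growing season (May by default) and annual mean one;
* per-sample lognormal noise applied as ONE factor common to all analytes
  of a sample, emulating flow-driven dilution/concentration, which
  dominates river chemistry variability. The factor is median-preserving.

Because the noise factor is common to the triplet, per-sample Redfield
percentages are untouched by it (they are scale-invariant); noise shows
up in concentrations, TSI and exceedance ratios. Independent analytical
error per analyte is *not* emulated (see the methods note).

A truth table computed analytically from the site medians (zone, TSI
basis, minimum-Si month) gives parameter-recovery tests an unambiguous
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stoichiometry, trophic
from .icep import critical_concentrations
from .units import CONSTANTS, from_molar, to_molar

#: µg SiO₂ per µg Si, the inverse of the ingest conversion.
SIO2_PER_SI = CONSTANTS.mass_sio2 / CONSTANTS.mass_si_precise

__all__ = ["SyntheticConfig", "generate", "make_redfield_site", "seasonal_factor"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults describe the emulated monitoring network."""

    n_sites: int = 50
    start_year: int = 2017
    end_year: int = 2024
    samples_per_month: int = 1
    lat_range: tuple[float, float] = (55.0, 70.0)
    #: site-median DIN in µg l⁻¹ at the southern and northern edge (log-linear between).
    din_range: tuple[float, float] = (2000.0, 50.0)
    #: site-median total P in µg l⁻¹ at the southern and northern edge.
    totp_range: tuple[float, float] = (120.0, 5.0)
    #: latitude-independent median Si in µg l⁻¹ and its between-site geometric SD.
    si_median: float = 2700.0
    si_site_gsd: float = 1.3
    si_trough_month: int = 5
    si_drawdown: float = 0.30
    #: coefficient of variation of the shared per-sample lognormal factor.
    noise_cv: float = 0.4
    missing_rate: float = 0.0
    #: fraction of DIN reported as nitrate+nitrite (the rest as ammonium).
    nitrate_fraction: float = 0.9
    #: fraction of sites reporting SiO₂ instead of elemental Si.
    sio2_site_fraction: float = 0.0
    #: specific runoff in l km⁻² d⁻¹ written to the site table.
    runoff: float = 8.64e5

    def validate(self) -> None:
        if self.n_sites < 1 or self.end_year < self.start_year:
            raise ValueError("need at least one site and a non-empty year range")
        if self.samples_per_month < 1:
            raise ValueError("samples_per_month must be >= 1")
        if not 0 <= self.si_drawdown < 1:
            raise ValueError("si_drawdown must lie in [0, 1)")
        if self.noise_cv < 0 or not 0 <= self.missing_rate < 1:
            raise ValueError("noise_cv must be >= 0 and missing_rate in [0, 1)")
        if min(self.din_range + self.totp_range) <= 0 or self.si_median <= 0:
            raise ValueError("all median concentrations must be positive")


def seasonal_factor(month, trough_month: int, depth: float):
    """Multiplicative seasonal Si factor: 1 − depth·cos(2π(m − trough)/12).

    Equal to 1 − depth at the trough month, 1 + depth half a year later,
    with an exact annual mean of 1 over the twelve calendar months.
    """
    month = np.asarray(month, dtype=float)
    out = 1.0 - depth * np.cos(2.0 * math.pi * (month - trough_month) / 12.0)
    return float(out) if out.ndim == 0 else out


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _loglinear(lat, lat_range, value_range):
    """Log-linear interpolation of a site median along the latitude gradient."""
    south, north = lat_range
    v_south, v_north = value_range
    t = (np.asarray(lat) - south) / (north - south)
    return np.exp(np.log(v_south) + t * (np.log(v_north) - np.log(v_south)))


def _truth_row(site_id, lat, din_med, totp_med, si_med, cfg: SyntheticConfig):
    din_u, totp_u, si_u = (to_molar(din_med, "N"), to_molar(totp_med, "P"),
                           to_molar(si_med, "Si"))
    comp = stoichiometry.compose(din_u, totp_u, si_u)
    assessment = trophic.select_basis_and_classify(din_u, totp_u)
    months = np.arange(1, 13)
    f = seasonal_factor(months, cfg.si_trough_month, cfg.si_drawdown)
    _, _, si_pct_m = stoichiometry.redfield_percentages(
        np.full(12, din_u), np.full(12, totp_u), si_u * f)
    min_idx = int(si_pct_m.argmin())
    din_0, totp_0 = critical_concentrations(si_med)
    return {
        "site_id": site_id, "lat": lat,
        "din_med": din_med, "totp_med": totp_med, "si_med": si_med,
        "n_pct": comp.n_pct, "p_pct": comp.p_pct, "si_pct": comp.si_pct,
        "zone": comp.zone.value,
        "basis": assessment.basis, "tsi": assessment.tsi,
        "tsi_class": assessment.tsi_class.value,
        "min_si_month": int(months[min_idx]),
        "min_si_pct": float(si_pct_m[min_idx]),
        "d_din": din_med / din_0, "d_totp": totp_med / totp_0,
    }


def generate(cfg: SyntheticConfig = SyntheticConfig(), seed: int = 0):
    """Generate ``(samples, sites, truth)`` DataFrames for one network draw.

    ``samples`` is in the raw ingest dialect (``no3_no2``/``nh4`` split,
    ``si`` or ``sio2``); ``sites`` carries coordinates and runoff;
    ``truth`` holds each site's analytic medians and derived classes.
    The seed fully determines every output.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n_sites

    lats = np.sort(rng.uniform(*cfg.lat_range, size=n))[::-1]
    site_ids = [f"S{i + 1:03d}" for i in range(n)]
    din_med = _loglinear(lats, cfg.lat_range, cfg.din_range)
    totp_med = _loglinear(lats, cfg.lat_range, cfg.totp_range)
    si_sigma = math.log(cfg.si_site_gsd)
    si_med = cfg.si_median * np.exp(rng.normal(0.0, si_sigma, size=n))
    reports_sio2 = rng.random(n) < cfg.sio2_site_fraction
    country = rng.choice(["SE", "NO", "FI"], size=n)

    sites = pd.DataFrame({
        "site_id": site_ids, "country": country,
        "lat": np.round(lats, 4),
        "lon": np.round(rng.uniform(5.0, 30.0, size=n), 4),
        "area_km2": np.round(np.exp(rng.uniform(math.log(50), math.log(50_000), size=n)), 1),
        "runoff": cfg.runoff,
    })
    truth = pd.DataFrame(
        [_truth_row(site_ids[i], lats[i], din_med[i], totp_med[i], si_med[i], cfg)
         for i in range(n)]
    )

    years = np.arange(cfg.start_year, cfg.end_year + 1)
    months = np.arange(1, 13)
    sigma = _lognormal_sigma(cfg.noise_cv)

    records = []
    for i in range(n):
        for year in years:
            for month in months:
                f_si = seasonal_factor(int(month), cfg.si_trough_month, cfg.si_drawdown)
                for k in range(cfg.samples_per_month):
                    day = 1 + int(rng.integers(0, 28))
                    noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                    din = din_med[i] * noise
                    totp = totp_med[i] * noise
                    si = si_med[i] * f_si * noise
                    rec = {
                        "site_id": site_ids[i],
                        "date": f"{year:04d}-{month:02d}-{day:02d}",
                        "no3_no2": din * cfg.nitrate_fraction,
                        "nh4": din * (1.0 - cfg.nitrate_fraction),
                        "totp": totp,
                        "si": np.nan, "sio2": np.nan,
                    }
                    if reports_sio2[i]:
                        rec["sio2"] = si * SIO2_PER_SI
                    else:
                        rec["si"] = si
                    if cfg.missing_rate > 0:
                        for col in ("no3_no2", "nh4", "totp", "si", "sio2"):
                            if rng.random() < cfg.missing_rate:
                                rec[col] = np.nan
                    records.append(rec)
    samples = pd.DataFrame.from_records(records)
    if not reports_sio2.any():
        samples = samples.drop(columns=["sio2"])
    return samples, sites, truth


_ZONE_ARCHETYPES = {
    stoichiometry.Zone.BALANCED: (33.34, 33.33, 33.33),
    stoichiometry.Zone.N_DEPLETED: (10.0, 45.0, 45.0),
    stoichiometry.Zone.P_DEPLETED: (45.0, 10.0, 45.0),
    stoichiometry.Zone.SI_DEPLETED: (45.0, 45.0, 10.0),
    stoichiometry.Zone.NP_DEPLETED: (15.0, 15.0, 70.0),
    stoichiometry.Zone.NSI_DEPLETED: (15.0, 70.0, 15.0),
    stoichiometry.Zone.PSI_DEPLETED: (70.0, 15.0, 15.0),
}

_TSI_CLASS_TARGET = {
    trophic.TsiClass.ULTRA_OLIGOTROPHIC: 25.0,
    trophic.TsiClass.OLIGOTROPHIC: 35.0,
    trophic.TsiClass.MESOTROPHIC: 45.0,
    trophic.TsiClass.EUTROPHIC: 55.0,
    trophic.TsiClass.HYPEREUTROPHIC: 65.0,
}


def make_redfield_site(zone, tsi_class=None):
    """Inverse design: a mass-concentration median triplet hitting a target zone
    (and optionally a target TSI class of its depleted-nutrient basis).

    Returns (din, totp, si) in µg l⁻¹. The construction picks an archetype
    composition inside the requested zone, converts it to a molar ray
    (compositions are scale-invariant), and scales along the ray so the
    depleted-nutrient TSI lands mid-class. The result is verified against
    the forward computations and the call fails if the target is missed.
    """
    zone = stoichiometry.Zone(zone)
    n_pct, p_pct, si_pct = _ZONE_ARCHETYPES[zone]
    # Un-normalised molar ray reproducing (n_pct, p_pct, si_pct) exactly.
    din_u = CONSTANTS.redfield_n * n_pct
    totp_u = CONSTANTS.redfield_p * p_pct
    si_u = CONSTANTS.redfield_si * si_pct

    scale = 1.0 / p_pct  # default: totp at 1 µmol l⁻¹ (31 µg l⁻¹), a realistic river
    if tsi_class is not None:
        tsi_class = trophic.TsiClass(tsi_class)
        target = _TSI_CLASS_TARGET[tsi_class]
        ratio = din_u / totp_u
        if ratio >= CONSTANTS.redfield_n:  # TotP basis: solve 4.15 + 14.42 ln(31 c totp) = target
            scale = math.exp((target - 4.15) / 14.42) / (CONSTANTS.mass_p * totp_u)
        else:  # DIN basis: solve 54.45 + 14.43 ln(14 c din / 1000) = target
            scale = math.exp((target - 54.45) / 14.43) * 1000.0 / (CONSTANTS.mass_n * din_u)

    din_u, totp_u, si_u = din_u * scale, totp_u * scale, si_u * scale
    comp = stoichiometry.compose(din_u, totp_u, si_u)
    if comp.zone != zone:
        raise ValueError(f"unreachable request: got zone {comp.zone}, wanted {zone}")
    if tsi_class is not None:
        got = trophic.select_basis_and_classify(din_u, totp_u).tsi_class
        if got != tsi_class:
            raise ValueError(f"unreachable request: got TSI class {got}, wanted {tsi_class}")
    return (from_molar(din_u, "N"), from_molar(totp_u, "P"), from_molar(si_u, "Si"))
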