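"""Index of coastal eutrophication potential (ICEP) and critical concentrations.

ICEP expresses the excess of N or P flux over what the available Si flux
could balance through diatom growth, as carbon-fixation potential of
non-siliceous (potentially harmful) phytoplankton:

    ICEP(P) = [PFlx/31 − SiFlx/(28·20)] · 106 · 12        N:P > 16
    ICEP(N) = [NFlx/(14·16) − SiFlx/(28·20)] · 106 · 12   N:P < 16

with fluxes in kg element km⁻² d⁻¹ and ICEP in kg C km⁻² d⁻¹. An ICEP of
zero marks balanced nutrient and Si inputs. Because flux = concentration ×
runoff, setting ICEP = 0 yields critical concentrations that need no flux
data at all:

    DIN_0  = (14·16)/(28·20) · Si = 0.4 · Si
    TotP_0 = 31/(28·20) · Si     ≈ 0.055 · Si

(all in µg l⁻¹), and exceedance ratios D = measured / critical, where
D > 1 is algebraically equivalent to a positive ICEP at any runoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import CONSTANTS, ElementConstants

__all__ = [
    "FluxTriplet",
    "CriticalConcResult",
    "icep_p",
    "icep_n",
    "icep",
    "critical_concentrations",
    "exceedance",
    "concentration_to_flux",
]


@dataclass(frozen=True)
class FluxTriplet:
    """Daily area-specific fluxes in kg element km⁻² d⁻¹."""

    nflx: float
    pflx: float
    siflx: float


@dataclass(frozen=True)
class CriticalConcResult:
    """Critical concentrations, exceedance ratios and (optionally) ICEP."""

    din_0: float
    totp_0: float
    d_din: float
    d_totp: float
    icep: float | None
    icep_basis: str  # "N" or "P"


def _check_nonneg(name, value):
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def icep_p(pflx, siflx, constants: ElementConstants = CONSTANTS):
    """ICEP on the P branch (kg C km⁻² d⁻¹); use when molar N:P ≥ 16."""
    _check_nonneg("pflx", pflx)
    _check_nonneg("siflx", siflx)
    si_div = constants.mass_si * constants.redfield_si
    return (pflx / constants.mass_p - siflx / si_div) * constants.carbon_factor


def icep_n(nflx, siflx, constants: ElementConstants = CONSTANTS):
    """ICEP on the N branch (kg C km⁻² d⁻¹); use when molar N:P < 16."""
    _check_nonneg("nflx", nflx)
    _check_nonneg("siflx", siflx)
    n_div = constants.mass_n * constants.redfield_n
    si_div = constants.mass_si * constants.redfield_si
    return (nflx / n_div - siflx / si_div) * constants.carbon_factor


def icep(f: FluxTriplet, np_molar_ratio: float,
         constants: ElementConstants = CONSTANTS) -> tuple[float, str]:
    """Branch-selected ICEP: the P branch at N:P ≥ 16, else the N branch."""
    if np_molar_ratio >= constants.redfield_n:
        return float(icep_p(f.pflx, f.siflx, constants)), "P"
    return float(icep_n(f.nflx, f.siflx, constants)), "N"


def critical_concentrations(si, constants: ElementConstants = CONSTANTS):
    """Critical (DIN_0, TotP_0) in µg l⁻¹ for a Si concentration in µg l⁻¹.

    These are the nutrient concentrations at which ICEP is exactly zero;
    with the default 16:1:20 ratio, DIN_0 = 0.4·Si and TotP_0 ≈ 0.055·Si.
    Homogeneous of degree 1 in Si.
    """
    _check_nonneg("si", si)
    si = np.asarray(si, dtype=float)
    si_div = constants.mass_si * constants.redfield_si
    din_0 = (constants.mass_n * constants.redfield_n / si_div) * si
    totp_0 = (constants.mass_p / si_div) * si
    if si.ndim == 0:
        return float(din_0), float(totp_0)
    return din_0, totp_0


def exceedance(measured, critical):
    """Exceedance ratio measured/critical; > 1 flags exceedance.

    A zero critical concentration (no Si) with a positive measurement is
    reported as +inf — unbounded eutrophication risk; 0/0 is NaN.
    """
    _check_nonneg("measured", measured)
    _check_nonneg("critical", critical)
    measured = np.asarray(measured, dtype=float)
    critical = np.asarray(critical, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = measured / critical
    if out.ndim == 0:
        return float(out)
    return out


def concentration_to_flux(conc_ugl, runoff_l_km2_d):
    """Flux in kg km⁻² d⁻¹ from concentration (µg l⁻¹) × runoff (l km⁻² d⁻¹)."""
    _check_nonneg("concentration", conc_ugl)
    _check_nonneg("runoff", runoff_l_km2_d)
    return np.asarray(conc_ugl, dtype=float) * np.asarray(runoff_l_km2_d, dtype=float) * 1e-9


def assess_critical(din, totp, si, runoff_l_km2_d=None,
                    constants: ElementConstants = CONSTANTS) -> CriticalConcResult:
    """Full critical-concentration assessment for one (DIN, TotP, Si) in µg l⁻¹.

    Computes DIN_0/TotP_0, both exceedance ratios, and — when runoff is
    supplied — the branch-selected ICEP. The branch follows the molar N:P
    ratio with the same tie rule as the trophic module (≥ 16 → P).
    """
    din_0, totp_0 = critical_concentrations(si, constants)
    d_din = exceedance(din, din_0)
    d_totp = exceedance(totp, totp_0)
    np_ratio = (din / constants.mass_n) / (totp / constants.mass_p) if totp > 0 else float("inf")
    basis = "P" if np_ratio >= constants.redfield_n else "N"
    icep_value = None
    if runoff_l_km2_d is not None:
        flux = FluxTriplet(
            nflx=float(concentration_to_flux(din, runoff_l_km2_d)),
            pflx=float(concentration_to_flux(totp, runoff_l_km2_d)),
            siflx=float(concentration_to_flux(si, runoff_l_km2_d)),
        )
        icep_value, basis = icep(flux, np_ratio, constants)
    return CriticalConcResult(din_0, totp_0, d_din, d_totp, icep_value, basis)
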