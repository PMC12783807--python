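"""Carlson-style trophic state index (TSI) for the Redfield-depleted nutrient.

The index is computed for total phosphorus when the molar N:P ratio
exceeds 16 (evidence of relative P depletion) and for dissolved inorganic
nitrogen otherwise:

    TSI(TotP) = 4.15 + 14.42 · ln(TotP in µg l⁻¹)      N:P > 16
    TSI(DIN)  = 54.45 + 14.43 · ln(DIN in mg l⁻¹)      N:P < 16

Both functions here take molar concentrations (µmol l⁻¹), converting with
the integer masses 31 and 14 internally, so the rest of the pipeline can
stay in molar units. A ratio of exactly 16 takes the P branch, making the
tie deterministic. Classes: TSI < 30 ultra-oligotrophic, 30–40
oligotrophic, 40–50 mesotrophic, 50–60 eutrophic, ≥ 60 hypereutrophic
(half-open on the left of the higher class).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .units import CONSTANTS, ElementConstants

__all__ = [
    "TsiClass",
    "TrophicAssessment",
    "tsi_totp",
    "tsi_din",
    "classify_tsi",
    "select_basis_and_classify",
    "TSI_CLASS_EDGES",
]

#: Left edges of the oligotrophic..hypereutrophic classes.
TSI_CLASS_EDGES = (30.0, 40.0, 50.0, 60.0)


class TsiClass(str, enum.Enum):
    ULTRA_OLIGOTROPHIC = "ultra_oligotrophic"
    OLIGOTROPHIC = "oligotrophic"
    MESOTROPHIC = "mesotrophic"
    EUTROPHIC = "eutrophic"
    HYPEREUTROPHIC = "hypereutrophic"


_CLASS_ORDER = (
    TsiClass.ULTRA_OLIGOTROPHIC,
    TsiClass.OLIGOTROPHIC,
    TsiClass.MESOTROPHIC,
    TsiClass.EUTROPHIC,
    TsiClass.HYPEREUTROPHIC,
)


@dataclass(frozen=True)
class TrophicAssessment:
    """TSI of the depleted nutrient plus the N:P ratio that selected it."""

    basis: str  # "TotP" or "DIN"
    tsi: float
    tsi_class: TsiClass
    np_molar_ratio: float


def tsi_totp(totp, constants: ElementConstants = CONSTANTS):
    """TSI(TotP) from total P in µmol l⁻¹; −inf at zero concentration."""
    totp = np.asarray(totp, dtype=float)
    with np.errstate(divide="ignore"):
        out = 4.15 + 14.42 * np.log(constants.mass_p * totp)
    return float(out) if out.ndim == 0 else out


def tsi_din(din, constants: ElementConstants = CONSTANTS):
    """TSI(DIN) from DIN in µmol l⁻¹; −inf at zero concentration."""
    din = np.asarray(din, dtype=float)
    with np.errstate(divide="ignore"):
        out = 54.45 + 14.43 * np.log(constants.mass_n * din / 1000.0)
    return float(out) if out.ndim == 0 else out


def classify_tsi(tsi) -> TsiClass:
    """Bin a TSI value into its trophic class (−inf → ultra-oligotrophic)."""
    tsi = np.asarray(tsi, dtype=float)

    def _one(v):
        if np.isnan(v):
            return None
        idx = int(np.searchsorted(TSI_CLASS_EDGES, v, side="right"))
        return _CLASS_ORDER[idx]

    if tsi.ndim == 0:
        cls = _one(float(tsi))
        if cls is None:
            raise ValueError("TSI is NaN")
        return cls
    return np.array([_one(v) for v in tsi.ravel()], dtype=object).reshape(tsi.shape)


def select_basis_and_classify(din, totp,
                              constants: ElementConstants = CONSTANTS) -> TrophicAssessment:
    """Choose TotP or DIN by the N:P = 16 rule and compute the matching TSI.

    ``din`` and ``totp`` are molar concentrations in µmol l⁻¹. N:P ≥ 16
    (including TotP = 0 with DIN > 0, where the ratio is infinite) takes
    the TotP branch; N:P < 16 takes the DIN branch.
    """
    din = float(din)
    totp = float(totp)
    if din <= 0 and totp <= 0:
        raise ValueError("trophic assessment needs DIN > 0 or TotP > 0")
    ratio = din / totp if totp > 0 else float("inf")
    if ratio >= constants.redfield_n:
        basis, value = "TotP", tsi_totp(totp, constants)
    else:
        basis, value = "DIN", tsi_din(din, constants)
    return TrophicAssessment(basis, value, classify_tsi(value), ratio)
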