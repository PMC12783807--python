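"""Redfield-scaled ternary coordinates and nutrient-depletion zones.

A molar triplet (DIN, TotP, Si) in µmol l⁻¹ is scaled by the Redfield
ratio 16:1:20 and expressed as three percentages summing to 100, so that a
sample with exactly Redfield stoichiometry plots at the ternary centroid
(33.3, 33.3, 33.3). An element whose Redfield percentage falls strictly
below a threshold (20% by convention) is called depleted; the depletion
zone is the set of depleted elements, or "balanced" when empty. Triple
depletion is impossible for thresholds below 100/3.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .units import CONSTANTS, ElementConstants

__all__ = [
    "Zone",
    "RedfieldComposition",
    "redfield_percentages",
    "classify_zone",
    "ternary_xy",
    "DEPLETION_THRESHOLD",
]

#: Conventional depletion threshold in percent.
DEPLETION_THRESHOLD = 20.0


class Zone(str, enum.Enum):
    """Nutrient-depletion class of a Redfield composition."""

    BALANCED = "balanced"
    N_DEPLETED = "N_depleted"
    P_DEPLETED = "P_depleted"
    SI_DEPLETED = "Si_depleted"
    NP_DEPLETED = "NP_depleted"
    NSI_DEPLETED = "NSi_depleted"
    PSI_DEPLETED = "PSi_depleted"


_ZONE_BY_KEY = {
    (): Zone.BALANCED,
    ("N",): Zone.N_DEPLETED,
    ("P",): Zone.P_DEPLETED,
    ("Si",): Zone.SI_DEPLETED,
    ("N", "P"): Zone.NP_DEPLETED,
    ("N", "Si"): Zone.NSI_DEPLETED,
    ("P", "Si"): Zone.PSI_DEPLETED,
}


@dataclass(frozen=True)
class RedfieldComposition:
    """Ternary percentages of a sample plus its depletion zone."""

    n_pct: float
    p_pct: float
    si_pct: float
    zone: Zone

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.n_pct, self.p_pct, self.si_pct)


def redfield_percentages(din, totp, si, constants: ElementConstants = CONSTANTS):
    """Redfield-scaled ternary percentages of a molar triplet.

    Parameters
    ----------
    din, totp, si
        Molar concentrations in µmol l⁻¹ (scalars or arrays).

    Returns
    -------
    (n_pct, p_pct, si_pct)
        Percentages summing to 100. The triplet 16:1:20 maps to
        (33.33..., 33.33..., 33.33...). All-zero triplets are rejected
        (scalar) or yield NaN (arrays).
    """
    din = np.asarray(din, dtype=float)
    totp = np.asarray(totp, dtype=float)
    si = np.asarray(si, dtype=float)
    if np.any(din < 0) or np.any(totp < 0) or np.any(si < 0):
        raise ValueError("molar concentrations must be non-negative")

    n_term = din / constants.redfield_n
    p_term = totp / constants.redfield_p
    si_term = si / constants.redfield_si
    denom = n_term + p_term + si_term

    scalar = denom.ndim == 0
    if scalar and denom == 0:
        raise ValueError("all-zero triplet: ternary composition undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom_safe = np.where(denom > 0, denom, np.nan)
        n_pct = 100.0 * n_term / denom_safe
        p_pct = 100.0 * p_term / denom_safe
        si_pct = 100.0 * si_term / denom_safe
    if scalar:
        return float(n_pct), float(p_pct), float(si_pct)
    return n_pct, p_pct, si_pct


def classify_zone(n_pct, p_pct, si_pct, threshold: float = DEPLETION_THRESHOLD):
    """Depletion zone of a ternary composition.

    Elements with a percentage strictly below ``threshold`` are depleted;
    a value exactly at the threshold is *not* depleted. Accepts scalars
    (returns :class:`Zone`) or arrays (returns an object array of zones,
    NaN compositions mapping to None).
    """
    if not 0 < threshold < 100.0 / 3.0:
        raise ValueError("depletion threshold must lie in (0, 33.33)")

    n_pct = np.asarray(n_pct, dtype=float)
    p_pct = np.asarray(p_pct, dtype=float)
    si_pct = np.asarray(si_pct, dtype=float)

    def _one(n, p, s):
        if math.isnan(n) or math.isnan(p) or math.isnan(s):
            return None
        depleted = tuple(
            name for name, v in (("N", n), ("P", p), ("Si", s)) if v < threshold
        )
        return _ZONE_BY_KEY[depleted]

    if n_pct.ndim == 0:
        zone = _one(float(n_pct), float(p_pct), float(si_pct))
        if zone is None:
            raise ValueError("composition contains NaN")
        return zone
    return np.array(
        [_one(n, p, s) for n, p, s in zip(n_pct.ravel(), p_pct.ravel(), si_pct.ravel())],
        dtype=object,
    ).reshape(n_pct.shape)


def compose(din, totp, si, threshold: float = DEPLETION_THRESHOLD,
            constants: ElementConstants = CONSTANTS) -> RedfieldComposition:
    """Convenience wrapper: molar triplet -> :class:`RedfieldComposition`."""
    n_pct, p_pct, si_pct = redfield_percentages(din, totp, si, constants)
    return RedfieldComposition(n_pct, p_pct, si_pct, classify_zone(n_pct, p_pct, si_pct, threshold))


def ternary_xy(n_pct, p_pct, si_pct):
    """Map ternary percentages to Cartesian coordinates in the unit triangle.

    Vertex layout (default rendering): N at the lower-left vertex (0, 0),
    P at the lower-right vertex (1, 0) and Si at the apex (0.5, √3/2), so
    jointly NP-depleted samples plot towards the top of the triangle. The
    centroid (33.3, 33.3, 33.3) maps to (0.5, √3/6).
    """
    n = np.asarray(n_pct, dtype=float) / 100.0
    p = np.asarray(p_pct, dtype=float) / 100.0
    s = np.asarray(si_pct, dtype=float) / 100.0
    x = p + 0.5 * s
    y = (math.sqrt(3.0) / 2.0) * s
    if x.ndim == 0:
        return float(x), float(y)
    return x, y
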