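"""Element constants and mass <-> molar conversions.

Every equation in the package pulls its constants from :data:`CONSTANTS`
(a single frozen instance) so that the Redfield Si term, molar masses and
the carbon conversion factor have exactly one source of truth.

Two sets of molar masses coexist deliberately:

* the integer masses 14 / 31 / 28 g mol⁻¹ for N, P and Si, used in every
  stoichiometric equation — these reproduce the published critical-
  concentration factors 0.4 (DIN) and ≈0.055 (TotP) exactly;
* the precise masses 28.08 / 60.08 g mol⁻¹, used only for converting
  reported SiO₂ to elemental Si, where the precise ratio is the stated
  conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ElementConstants",
    "CONSTANTS",
    "with_si_term",
    "to_molar",
    "from_molar",
    "si_from_sio2",
]


@dataclass(frozen=True)
class ElementConstants:
    """Molar masses (g mol⁻¹), Redfield terms and the carbon factor."""

    mass_n: float = 14.0
    mass_p: float = 31.0
    mass_si: float = 28.0
    mass_si_precise: float = 28.08
    mass_sio2: float = 60.08
    redfield_n: float = 16.0
    redfield_p: float = 1.0
    redfield_si: float = 20.0
    #: 106 mol C per Redfield mol P, times 12 g C mol⁻¹.
    carbon_factor: float = 106.0 * 12.0

    def mass_of(self, element: str) -> float:
        try:
            return {"N": self.mass_n, "P": self.mass_p, "Si": self.mass_si}[element]
        except KeyError:
            raise ValueError(f"unknown element {element!r}; expected 'N', 'P' or 'Si'") from None


CONSTANTS = ElementConstants()


def with_si_term(si_term: float, base: ElementConstants = CONSTANTS) -> ElementConstants:
    """Return constants with a different Redfield Si term (e.g. 16, 17, 20 or 40).

    The 16:1:20 default matches SDG 14.1.1a reporting; lower Si terms suit
    marine diatom stoichiometry and higher ones freshwater assemblages.
    """
    if si_term <= 0:
        raise ValueError("Redfield Si term must be positive")
    return replace(base, redfield_si=float(si_term))


def to_molar(mass_conc, element: str, constants: ElementConstants = CONSTANTS):
    """Convert a mass concentration in µg l⁻¹ to µmol l⁻¹.

    Uses the integer molar masses (14, 31, 28). Accepts scalars or arrays.
    """
    return mass_conc / constants.mass_of(element)


def from_molar(molar_conc, element: str, constants: ElementConstants = CONSTANTS):
    """Convert µmol l⁻¹ back to µg l⁻¹ (inverse of :func:`to_molar`)."""
    return molar_conc * constants.mass_of(element)


def si_from_sio2(sio2, constants: ElementConstants = CONSTANTS):
    """Convert µg SiO₂ l⁻¹ to µg Si l⁻¹ using the precise molar-mass ratio 28.08/60.08."""
    import numpy as np

    if np.any(np.asarray(sio2) < 0):
        raise ValueError("SiO2 concentration must be non-negative")
    return sio2 * (constants.mass_si_precise / constants.mass_sio2)
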