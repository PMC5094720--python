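"""Element registry and X-ray cross sections.

Holds the atomic data the quantification needs (atomic number, molar mass,
characteristic fluorescence-line energies) and a parametric total mass
attenuation coefficient provider used for self-absorption corrections.

The provider decomposes into photoelectric, incoherent (Compton) and coherent
(Rayleigh) components so each can be inspected or checked independently.  The
photoelectric term is a smooth Z/E power law (no absorption-edge structure),
the incoherent term is Klein-Nishina scattering off Z electrons per atom, and
the coherent term is a small parametric correction.  This is a self-consistent
model, adequate for a pipeline whose calibration and quantification share the
same provider; it is not a replacement for tabulated databases when absolute
cross sections matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ElementRecord",
    "REGISTRY",
    "DETECTABLE_ELEMENTS",
    "line_energy",
    "atomic_mass",
    "ParametricCrossSections",
    "mixture_attenuation",
]


@dataclass(frozen=True)
class ElementRecord:
    """Atomic data for one element.

    ``line_kev`` is the energy of the effective fluorescence line used for
    both simulation and fitting (K-alpha up to Sr, L-alpha for Pb);
    ``line_group`` records which shell that line belongs to.
    """

    symbol: str
    z: int
    mass: float  # g/mol
    line_kev: float | None = None
    line_group: str | None = None


_RECORDS = [
    # matrix / organic residual elements (no fluorescence line in band)
    ElementRecord("H", 1, 1.008),
    ElementRecord("C", 6, 12.011),
    ElementRecord("N", 7, 14.007),
    ElementRecord("O", 8, 15.999),
    ElementRecord("Na", 11, 22.990),
    ElementRecord("Mg", 12, 24.305),
    # detectable elements, K lines
    ElementRecord("P", 15, 30.974, 2.014, "K"),
    ElementRecord("S", 16, 32.06, 2.308, "K"),
    ElementRecord("Cl", 17, 35.45, 2.622, "K"),
    ElementRecord("K", 19, 39.098, 3.314, "K"),
    ElementRecord("Ca", 20, 40.078, 3.692, "K"),
    ElementRecord("Mn", 25, 54.938, 5.899, "K"),
    ElementRecord("Fe", 26, 55.845, 6.404, "K"),
    ElementRecord("Co", 27, 58.933, 6.930, "K"),
    ElementRecord("Ni", 28, 58.693, 7.478, "K"),
    ElementRecord("Cu", 29, 63.546, 8.048, "K"),
    ElementRecord("Zn", 30, 65.38, 8.639, "K"),
    ElementRecord("Se", 34, 78.971, 11.222, "K"),
    ElementRecord("Br", 35, 79.904, 11.924, "K"),
    ElementRecord("Rb", 37, 85.468, 13.396, "K"),
    ElementRecord("Sr", 38, 87.62, 14.165, "K"),
    # Pb quantified through its L-alpha line
    ElementRecord("Pb", 82, 207.2, 10.552, "L"),
]

REGISTRY: Mapping[str, ElementRecord] = {r.symbol: r for r in _RECORDS}

#: The 15 elements quantified in embedded single cells.
DETECTABLE_ELEMENTS = (
    "P", "S", "Cl", "K", "Ca", "Mn", "Fe", "Co",
    "Ni", "Cu", "Zn", "Se", "Br", "Sr", "Pb",
)


def line_energy(symbol: str) -> float:
    """Energy (keV) of the effective fluorescence line of ``symbol``."""
    rec = REGISTRY.get(symbol)
    if rec is None or rec.line_kev is None:
        raise KeyError(f"no fluorescence line registered for element {symbol!r}")
    return rec.line_kev


def atomic_mass(symbol: str) -> float:
    """Molar mass in g/mol."""
    rec = REGISTRY.get(symbol)
    if rec is None:
        raise KeyError(f"unknown element symbol {symbol!r}")
    return rec.mass


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------

_R_E_CM = 2.8179403262e-13  # classical electron radius, cm
_AVOGADRO = 6.02214076e23
_MEC2_KEV = 510.99895


def klein_nishina_cm2(energy_kev: float | np.ndarray) -> float | np.ndarray:
    """Total Klein-Nishina cross section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / _MEC2_KEV
    one = 1.0 + 2.0 * k
    term1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / one - np.log(one) / k)
    term2 = np.log(one) / (2.0 * k)
    term3 = (1.0 + 3.0 * k) / one**2
    sigma = 2.0 * np.pi * _R_E_CM**2 * (term1 + term2 - term3)
    return float(sigma) if np.isscalar(energy_kev) else sigma


class ParametricCrossSections:
    """Smooth parametric total mass attenuation coefficients, cm^2/g.

    Components (all per element, mixture values by mass-fraction weighting):

    * photoelectric: ``c_pe * Z^4.3 / (A * E^3)`` -- the dominant term below
      ~20 keV, normalised so transition-metal values at 10 keV land in the
      right range;
    * incoherent: Klein-Nishina per electron times ``N_A * Z / A``;
    * coherent: ``c_coh * Z^2.5 / (A * E^1.9)``.

    No absorption-edge jumps are modelled.
    """

    def __init__(self, c_pe: float = 7.75, c_coh: float = 1.2):
        self.c_pe = c_pe
        self.c_coh = c_coh

    def photoelectric(self, symbol: str, energy_kev: float) -> float:
        rec = REGISTRY[symbol]
        return self.c_pe * rec.z**4.3 / (rec.mass * energy_kev**3)

    def incoherent(self, symbol: str, energy_kev: float) -> float:
        rec = REGISTRY[symbol]
        return _AVOGADRO * rec.z / rec.mass * klein_nishina_cm2(energy_kev)

    def coherent(self, symbol: str, energy_kev: float) -> float:
        rec = REGISTRY[symbol]
        return self.c_coh * rec.z**2.5 / (rec.mass * energy_kev**1.9)

    def elemental(self, symbol: str, energy_kev: float) -> float:
        """Total mass attenuation coefficient of a pure element, cm^2/g."""
        if symbol not in REGISTRY:
            raise KeyError(f"unknown element symbol {symbol!r}")
        if energy_kev <= 0:
            raise ValueError("energy must be positive")
        return (
            self.photoelectric(symbol, energy_kev)
            + self.incoherent(symbol, energy_kev)
            + self.coherent(symbol, energy_kev)
        )

    def __call__(self, composition: Mapping[str, float], energy_kev: float) -> float:
        """Mixture total mass attenuation coefficient, cm^2/g.

        ``composition`` maps element symbol to mass fraction; fractions are
        used as given (callers normalise).
        """
        return sum(w * self.elemental(sym, energy_kev) for sym, w in composition.items())


def mixture_attenuation(
    composition: Mapping[str, float],
    energy_kev: float,
    provider=None,
) -> float:
    """Mass-fraction-weighted mixture attenuation coefficient (cm^2/g)."""
    if provider is None:
        provider = ParametricCrossSections()
    return provider(composition, energy_kev)
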