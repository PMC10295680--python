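"""Radiolytic yield (G-value) bookkeeping for N2O-saturated aqueous crocin.

Water radiolysis produces a fixed cocktail of primary species per joule of
absorbed dose.  In N2O-saturated solution the hydrated electron (and, slowly,
the H atom) is converted to OH•, so the effective oxidizing yield is the sum
of the e-_aq and OH• primary yields.  This module stores the primary yields,
converts dose to radical concentration under the dilute-water convention
1 Gy = 1 J/L, derives the dose per pulse from hydrated-electron dosimetry,
and evaluates the calculated crocin-consumption / product yields of the
pulse, gamma-disproportionation and Ag+ reaction schemes.

Yields are stored in SI mol/J; use :func:`crocin_radiolysis.units.g_in_display_units`
(or :meth:`PrimaryYields.in_display_units`) for the conventional 1e-7 mol/J
printing unit.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

from .units import G_DISPLAY_UNIT

__all__ = [
    "PrimaryYields",
    "WATER_PRIMARY_YIELDS",
    "Scheme",
    "oh_yield",
    "dose_to_concentration",
    "dose_from_eaq_absorbance",
    "scheme_yield",
    "dimer_yield",
]


@dataclass(frozen=True)
class PrimaryYields:
    """Primary radiolytic yields of water, in mol/J.

    The defaults are the standard yields at a scavenging factor of 1e-7 s^-1
    (about 100 ns after the pulse, once spur reactions are over):
    e-_aq 2.8, H+ 2.8, H• 0.62, H2 0.47, OH• 2.8, H2O2 0.73, all in
    1e-7 mol/J.
    """

    e_aq: float = 2.8e-7
    h_plus: float = 2.8e-7
    h_atom: float = 0.62e-7
    h2: float = 0.47e-7
    oh: float = 2.8e-7
    h2o2: float = 0.73e-7

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"yield {f.name} must be >= 0, got {value}")

    def scaled(self, factor: float) -> "PrimaryYields":
        """Return a copy with every yield multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return PrimaryYields(**{f.name: getattr(self, f.name) * factor for f in fields(self)})

    def in_display_units(self) -> dict[str, float]:
        """All yields expressed in the conventional 1e-7 mol/J unit."""
        return {f.name: getattr(self, f.name) / G_DISPLAY_UNIT for f in fields(self)}


#: Default water primary yields (scavenging factor 1e-7 s^-1).
WATER_PRIMARY_YIELDS = PrimaryYields()


class Scheme(str, Enum):
    """Reaction-scheme bookkeeping for the calculated consumption yields.

    ``PULSE_N2O``
        Pulse radiolysis in N2O-saturated solution: every oxidizing
        equivalent (e-_aq converted by N2O, OH•, and the slow H• channel)
        consumes one crocin, giving the oxidized-radical yield.
    ``GAMMA_N2O_DISPROPORTIONATION``
        Steady-state gamma radiolysis: radicals disproportionate (two
        radicals -> one twice-oxidized molecule + one regenerated crocin),
        halving the consumption, while H2O2 slowly oxidizes crocin as well.
    ``GAMMA_AG_PLUS``
        Gamma radiolysis with Ag+ scavenging H• (and the resulting silver
        atoms regenerating crocin), again followed by disproportionation.
    """

    PULSE_N2O = "pulse_N2O"
    GAMMA_N2O_DISPROPORTIONATION = "gamma_N2O_disproportionation"
    GAMMA_AG_PLUS = "gamma_Ag_plus"


def oh_yield(yields: PrimaryYields = WATER_PRIMARY_YIELDS) -> float:
    """Effective OH• yield in N2O-saturated solution, mol/J.

    N2O converts hydrated electrons to OH•, so G(OH•) = G(e-_aq) + G(OH•).
    The small H-atom channel is slow and excluded from this sum.
    """
    return yields.e_aq + yields.oh


def dose_to_concentration(dose_gy: float, g: float) -> float:
    """Concentration (mol/L) of a species with yield ``g`` after ``dose_gy``.

    Uses the dilute-aqueous convention 1 Gy = 1 J/L (density 1 kg/L), so the
    concentration is simply dose x G.
    """
    if dose_gy < 0:
        raise ValueError("dose must be >= 0")
    if g < 0:
        raise ValueError("yield must be >= 0")
    return dose_gy * g


def dose_from_eaq_absorbance(
    a660: float,
    eps660: float = 18_000.0,
    path_cm: float = 0.5,
    g_eaq: float = 3.3e-7,
) -> float:
    """Dose per pulse (Gy) from the hydrated-electron absorbance at 660 nm.

    Inverts Beer-Lambert plus the dose-concentration relation:
    A = eps * (G * D) * l  =>  D = A / (eps * l * G).

    Defaults are the standard dosimetry parameters: eps(660 nm) =
    18,000 M^-1 cm^-1 and G(e-_aq) = 3.3e-7 mol/J at 5 ns.
    """
    if eps660 <= 0:
        raise ValueError("eps660 must be > 0")
    if path_cm <= 0:
        raise ValueError("path_cm must be > 0")
    if g_eaq <= 0:
        raise ValueError("g_eaq must be > 0")
    if a660 < 0:
        raise ValueError("absorbance must be >= 0")
    return a660 / (eps660 * path_cm * g_eaq)


def scheme_yield(scheme: Scheme | str, yields: PrimaryYields = WATER_PRIMARY_YIELDS) -> float:
    """Calculated crocin consumption-or-product yield (mol/J) for a scheme.

    - pulse_N2O:  G(e-_aq) + G(OH•) + G(H•)            (radical formation)
    - gamma_N2O_disproportionation:
                  1/2 (G(e-_aq) + G(OH•) + G(H•) + 2 G(H2O2))
    - gamma_Ag_plus: 1/2 (G(e-_aq) + G(OH•) - G(H•))   (H• diverted to Ag+,
      silver atoms regenerate crocin, then disproportionation halves the
      remainder)
    """
    scheme = Scheme(scheme)
    if scheme is Scheme.PULSE_N2O:
        return yields.e_aq + yields.oh + yields.h_atom
    if scheme is Scheme.GAMMA_N2O_DISPROPORTIONATION:
        return 0.5 * (yields.e_aq + yields.oh + yields.h_atom + 2.0 * yields.h2o2)
    if scheme is Scheme.GAMMA_AG_PLUS:
        return 0.5 * (yields.e_aq + yields.oh - yields.h_atom)
    raise ValueError(f"unknown scheme {scheme!r}")  # pragma: no cover


def dimer_yield(yields: PrimaryYields = WATER_PRIMARY_YIELDS) -> float:
    """Radical-dimer yield in pulse radiolysis: half the radical yield."""
    return 0.5 * scheme_yield(Scheme.PULSE_N2O, yields)
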