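"""Thermochemical arithmetic on top of external quantum-chemistry outputs.

Two small pieces of algebra and one data table:

* the Wertz-corrected association free energy in solution,

      dG_corr = dG_pcm - 0.5 (dG_gas - dH_gas) + kB T,

  which empirically halves the gas-phase entropy penalty of association in
  a continuum solvent (the +kB T term cancels the PV contribution to the
  gas-phase enthalpy convention);

* the one-equivalent redox deduction E = E_ref + dG (a reaction free energy
  in eV numerically equals a potential shift in V for one H-atom/electron
  equivalent), used to place the crocin-model couple against the OH•/H2O
  reference at ~2.0 V vs NHE;

* the table of computed molar reaction free energies (eV) for H-abstraction,
  dimerization, disproportionation and complexation of the crocetin
  dimethyl-ester model, shipped as package data.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .units import KB_EV_PER_K

__all__ = [
    "ThermoRecord",
    "RedoxCouple",
    "OH_WATER_POTENTIAL_VNHE",
    "wertz_correct",
    "redox_potential",
    "reaction_free_energy",
    "list_reactions",
]

#: Reference redox potential E(OH•/H2O) at pH 7, V vs NHE.
OH_WATER_POTENTIAL_VNHE = 2.0


@dataclass(frozen=True)
class ThermoRecord:
    """Free energies (eV) of one reaction: continuum-solvent and gas phase."""

    delta_g_pcm_ev: float
    delta_g_gas_ev: float
    delta_h_gas_ev: float
    temperature_k: float = 295.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class RedoxCouple:
    """Reaction free energy per equivalent and the reference potential."""

    delta_g_ev: float
    e_ref_vnhe: float = OH_WATER_POTENTIAL_VNHE
    label: str = ""


def wertz_correct(record: ThermoRecord) -> float:
    """Wertz-corrected association free energy in eV.

    Returns dG_pcm - 0.5 (dG_gas - dH_gas) + kB T, with kB T in eV at the
    record's temperature (per-particle form of the molar RT term).
    """
    return (
        record.delta_g_pcm_ev
        - 0.5 * (record.delta_g_gas_ev - record.delta_h_gas_ev)
        + KB_EV_PER_K * record.temperature_k
    )


def redox_potential(couple: RedoxCouple) -> float:
    """Couple potential in V vs NHE under the one-equivalent convention.

    E = E_ref + dG: a more negative scavenging free energy places the
    couple further below the reference.
    """
    return couple.e_ref_vnhe + couple.delta_g_ev


def _normalize(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "", label.lower())


@lru_cache(maxsize=1)
def _load_table() -> tuple[dict[str, float], dict[str, str], dict[str, bool]]:
    values: dict[str, float] = {}
    aliases: dict[str, str] = {}
    lower_bounds: dict[str, bool] = {}
    path = resources.files("crocin_radiolysis.data") / "reaction_free_energies.csv"
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"]
            values[label] = float(row["delta_g_ev"])
            lower_bounds[label] = bool(int(row["lower_bound"]))
            aliases[_normalize(label)] = label
    return values, aliases, lower_bounds


def reaction_free_energy(label: str) -> float:
    """Tabulated reaction free energy (eV) for a crocetin-model reaction.

    Lookup is exact on the canonical label, with a punctuation-insensitive
    fallback (e.g. "Me2crocetin+OH->R.Ca" matches the canonical
    "Me2-crocetin + OH -> R.Ca").  Entries marked as lower bounds (singlet
    diradical species) return the bound value.
    """
    values, aliases, _ = _load_table()
    if label in values:
        return values[label]
    canonical = aliases.get(_normalize(label))
    if canonical is None:
        raise KeyError(f"unknown reaction {label!r}; see list_reactions()")
    return values[canonical]


def is_lower_bound(label: str) -> bool:
    """Whether the tabulated value is a lower bound rather than an estimate."""
    values, aliases, lower_bounds = _load_table()
    canonical = label if label in values else aliases.get(_normalize(label))
    if canonical is None:
        raise KeyError(f"unknown reaction {label!r}")
    return lower_bounds[canonical]


def list_reactions() -> list[str]:
    """Canonical labels of all tabulated reactions."""
    values, _, _ = _load_table()
    return list(values)
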