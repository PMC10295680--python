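"""UV-vis spectra from electronic-transition line lists.

A Monte-Carlo trajectory provides, at every recorded configuration, a list
of electronic transitions (excitation energy, oscillator strength, spin
expectation <S^2>).  The absorption spectrum is the configuration average
of Gaussian-broadened lines: each line contributes a Gaussian in the energy
domain centered at its excitation energy, with area proportional to its
oscillator strength and a prescribed full width at half maximum.  Lines
whose <S^2> exceeds the ground-state value by more than the spin-screening
parameter are spin-contaminated artifacts of the one-determinant reference
and are discarded before the convolution.

Species and conformer spectra are combined as probability-weighted sums;
helper functions build the standard weight patterns (equal vs sugar-driven
monomer probabilities, and their binomial extension to radical dimers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .spectral_calibration import Spectrum
from .units import HC_EV_NM

__all__ = [
    "TransitionLine",
    "LineEnsemble",
    "MixingWeights",
    "subsample",
    "spin_screen",
    "convolve",
    "mix",
    "monomer_to_dimer_weights",
    "sugar_driven_weights",
    "DEFAULT_FWHM_EV",
]

#: Gaussian fwhm registry (eV): line broadening of single optimized
#: structures; intense bands and weak high-energy bands of a simulation;
#: weak low-energy bands of a simulation.
DEFAULT_FWHM_EV = {
    "optimized_structure": 0.70,
    "intense": 0.50,
    "weak_high_energy": 0.50,
    "weak_low_energy": 0.20,
}

_LINE_COLUMNS = ("config_index", "energy_ev", "osc_strength", "s2")


@dataclass(frozen=True)
class TransitionLine:
    """One electronic transition of one sampled configuration."""

    energy_ev: float
    osc_strength: float
    s2: float
    config_index: int

    def __post_init__(self) -> None:
        if self.energy_ev <= 0:
            raise ValueError("excitation energy must be > 0")
        if self.osc_strength < 0:
            raise ValueError("oscillator strength must be >= 0")
        if self.s2 < 0:
            raise ValueError("<S^2> must be >= 0")


@dataclass
class LineEnsemble:
    """Transition lines grouped by Monte-Carlo configuration.

    ``lines`` holds columns config_index, energy_ev, osc_strength, s2.
    ``ground_s2`` is the ground-state <S^2> of the species (0 for closed
    shells, 0.75 for a doublet radical); the MC metadata records how the
    configurations were sampled.
    """

    lines: pd.DataFrame
    ground_s2: float
    species: str = ""
    total_steps: int = 0
    burn_in: int = 0
    stride: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.lines, Iterable) and not isinstance(self.lines, pd.DataFrame):
            self.lines = pd.DataFrame(
                [(l.config_index, l.energy_ev, l.osc_strength, l.s2) for l in self.lines],
                columns=list(_LINE_COLUMNS),
            )
        missing = set(_LINE_COLUMNS) - set(self.lines.columns)
        if missing:
            raise ValueError(f"line table missing columns {sorted(missing)}")
        if self.ground_s2 < 0:
            raise ValueError("ground-state <S^2> must be >= 0")
        if len(self.lines) and (self.lines["energy_ev"] <= 0).any():
            raise ValueError("excitation energies must be > 0")
        if len(self.lines) and (self.lines["osc_strength"] < 0).any():
            raise ValueError("oscillator strengths must be >= 0")

    @property
    def n_configurations(self) -> int:
        return int(self.lines["config_index"].nunique())

    def config_indices(self) -> np.ndarray:
        return np.sort(self.lines["config_index"].unique())


def subsample(ensemble: LineEnsemble, burn_in: int, stride: int) -> LineEnsemble:
    """Uniform trajectory subsampling: drop the burn-in, keep every
    ``stride``-th configuration thereafter.

    With configurations indexed 0..total-1, keeps indices i >= burn_in with
    (i - burn_in) % stride == 0, i.e. (total - burn_in) / stride
    configurations for an evenly divisible window.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    total = ensemble.total_steps or int(ensemble.lines["config_index"].max()) + 1
    if burn_in >= total:
        raise ValueError(f"burn-in {burn_in} leaves no configurations of {total}")
    idx = ensemble.lines["config_index"]
    keep = (idx >= burn_in) & ((idx - burn_in) % stride == 0)
    return replace(
        ensemble,
        lines=ensemble.lines.loc[keep].reset_index(drop=True),
        burn_in=burn_in,
        stride=stride,
    )


def spin_screen(
    ensemble: LineEnsemble, parameter: float, mode: str = "relative"
) -> LineEnsemble:
    """Discard spin-contaminated lines.

    A line is kept when its <S^2> does not exceed the ground-state value by
    more than the screening parameter — interpreted as a relative excess
    (cutoff = ground * (1 + parameter), the default; a "20%" screen) or an
    absolute one (cutoff = ground + parameter).
    """
    if parameter < 0:
        raise ValueError("screening parameter must be >= 0")
    if mode == "relative":
        cutoff = ensemble.ground_s2 * (1.0 + parameter)
    elif mode == "absolute":
        cutoff = ensemble.ground_s2 + parameter
    else:
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    keep = ensemble.lines["s2"] <= cutoff + 1e-12
    return replace(ensemble, lines=ensemble.lines.loc[keep].reset_index(drop=True))


def convolve(
    ensemble: LineEnsemble,
    fwhm_ev: float,
    grid_nm: np.ndarray | None = None,
) -> Spectrum:
    """Configuration-averaged Gaussian broadening of the line list.

    Each line contributes a normalized Gaussian in the energy domain,
    centered at its excitation energy with the given fwhm and area equal to
    its oscillator strength (f is an integrated intensity).  Per-
    configuration sums are averaged over configurations and the result is
    evaluated on the wavelength grid (default 200-900 nm at 1 nm).  The
    intensity unit is oscillator strength per eV.
    """
    if fwhm_ev <= 0:
        raise ValueError("fwhm must be > 0")
    if grid_nm is None:
        grid_nm = np.arange(200.0, 901.0)
    grid_nm = np.asarray(grid_nm, dtype=float)
    energies_grid = HC_EV_NM / grid_nm

    if len(ensemble.lines) == 0:
        warnings.warn("empty line ensemble: returning a zero spectrum", stacklevel=2)
        return Spectrum(grid_nm, np.zeros_like(grid_nm), kind="intensity",
                        species=ensemble.species)

    sigma = fwhm_ev / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    e0 = ensemble.lines["energy_ev"].to_numpy()
    f = ensemble.lines["osc_strength"].to_numpy()
    n_cfg = ensemble.n_configurations
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    gauss = np.exp(-0.5 * ((energies_grid[None, :] - e0[:, None]) / sigma) ** 2)
    values = norm * (f @ gauss) / n_cfg
    return Spectrum(grid_nm, values, kind="intensity", species=ensemble.species)


@dataclass(frozen=True)
class MixingWeights:
    """Probabilities for combining species/conformer spectra (sum to 1)."""

    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be >= 0")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        object.__setattr__(self, "weights", w)

    def __getitem__(self, label: str) -> float:
        return self.weights[label]

    def items(self):
        return self.weights.items()


def mix(spectra: Mapping[str, Spectrum], weights: MixingWeights | Mapping[str, float]) -> Spectrum:
    """Pointwise probability-weighted sum of species spectra (shared grid)."""
    if not isinstance(weights, MixingWeights):
        weights = MixingWeights(weights)
    labels = list(weights.weights)
    missing = [lab for lab in labels if lab not in spectra]
    if missing:
        raise KeyError(f"no spectrum for weighted species {missing}")
    grid = spectra[labels[0]].wavelength_nm
    kind = spectra[labels[0]].kind
    out = np.zeros_like(grid, dtype=float)
    for lab in labels:
        s = spectra[lab]
        if s.wavelength_nm.shape != grid.shape or not np.allclose(s.wavelength_nm, grid):
            raise ValueError("all spectra must share the wavelength grid")
        out += weights[lab] * s.values
    return Spectrum(grid, out, kind=kind)


def monomer_to_dimer_weights(p_a: float, p_b: float) -> MixingWeights:
    """Binomial dimer probabilities from monomer formation probabilities.

    Independent pairing of radicals with probabilities (p_a, p_b) gives
    dimers aa : ab : bb = p_a^2 : 2 p_a p_b : p_b^2.
    """
    if p_a < 0 or p_b < 0 or abs(p_a + p_b - 1.0) > 1e-12:
        raise ValueError("(p_a, p_b) must be a probability pair summing to 1")
    return MixingWeights({"aa": p_a * p_a, "ab": 2.0 * p_a * p_b, "bb": p_b * p_b})


def sugar_driven_weights(chain_encounter_fraction: float) -> MixingWeights:
    """Monomer probabilities under the sugar-driven abstraction mechanism.

    The OH radical first meets either the polyene chain (fraction f) or a
    sugar substituent (1 - f).  Chain encounters split evenly between the
    two methyl sites; sugar encounters cannot abstract from the sugar and
    migrate to the nearest chain methyl, all feeding site a:

        p_a = (1 - f) + f/2,   p_b = f/2.

    f = 1 recovers the no-sugar-influence limit (1/2, 1/2); f = 1/3 the
    sugar-driven (5/6, 1/6) pattern.
    """
    f = chain_encounter_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("chain encounter fraction must be in [0, 1]")
    return MixingWeights({"a": 1.0 - 0.5 * f, "b": 0.5 * f})
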