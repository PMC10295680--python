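"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every data stream the pipeline consumes — transient-absorbance
traces, dose-indexed absorption spectra, crocin-like absorptivity spectra
and electronic-transition line lists — from explicit recipes, so that each
fitting stage can be exercised as a parameter-recovery round trip without
any experimental input.

Defaults reproduce the study conditions: 97 Gy per pulse, G(OH•) = 5.6e-7
mol/J (so [OH•] = 5.4e-5 M), crocin at its 0.13 mM solubility limit for the
kinetics, 0.057 mM for the gamma series in a 1 mm cell, k2 = 3.4e10
M^-1 s^-1 formation, 2k = 3.7e9 M^-1 s^-1 radical recombination, ±5%
multiplicative absorbance noise, a hydrated-electron bump confined to the
first ~50 ns, and absorptivity fixtures with the 441 nm main band
(1.35e5 M^-1 cm^-1), 460 nm shoulder, weak 333/250 nm bands and the
product bands at 330/441 nm crossing crocin at the 375 nm isosbestic point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticTrace
from .spectral_calibration import Spectrum
from .spectrum_synthesis import LineEnsemble

__all__ = [
    "GaussianBand",
    "TraceRecipe",
    "SpectrumRecipe",
    "LineListRecipe",
    "gen_formation_trace",
    "gen_decay_trace",
    "gen_crocin_like_spectrum",
    "gen_product_like_spectrum",
    "gen_radical_like_spectrum",
    "gen_dose_series",
    "gen_linelist",
    "DEFAULT_GRID_NM",
]

DEFAULT_GRID_NM = np.arange(200.0, 901.0)

_SIGMA_PER_FWHM = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GaussianBand(NamedTuple):
    """One absorption band: center (nm), peak amplitude (M^-1 cm^-1), fwhm (nm)."""

    center_nm: float
    amplitude: float
    fwhm_nm: float


def _band_values(grid: np.ndarray, bands: Sequence[GaussianBand]) -> np.ndarray:
    out = np.zeros_like(grid, dtype=float)
    for center, amp, fwhm in bands:
        sigma = fwhm * _SIGMA_PER_FWHM
        out += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return out


@dataclass
class TraceRecipe:
    """Recipe for a transient-absorbance trace at one wavelength.

    ``mechanism`` selects pseudo-first-order radical formation or
    second-order radical decay.  The hydrated-electron bump is an additive
    transient amp * (1 - exp(-t/rise)) * exp(-t/decay); with the default
    2 ns rise and 8 ns decay (the electron lifetime under N2O saturation is
    a few ns) it is below 1% of its peak by 50 ns, so fits starting at
    50 ns see a bump-free trace.  Noise is multiplicative Gaussian at
    ``noise_fraction`` (the stated ±5% absorbance uncertainty).
    """

    mechanism: str = "formation"
    wavelength_nm: float = 678.0
    path_cm: float = 0.5
    noise_fraction: float = 0.05
    seed: int = 0
    times_s: np.ndarray | None = None
    # formation parameters
    k2: float = 3.4e10  # M^-1 s^-1
    scavenger_conc: float = 1.3e-4  # M, crocin at the solubility limit
    c_oh0: float = 5.4e-5  # M, OH radical burst at 97 Gy
    eps_scavenger: float = 0.0  # M^-1 cm^-1 at the trace wavelength
    eps_radical: float = 6230.0
    # bump parameters
    bump_amplitude: float = 0.05
    bump_rise_s: float = 2e-9
    bump_decay_s: float = 8e-9
    # decay parameters
    a0: float = 0.168
    rate_2k: float = 3.7e9  # M^-1 s^-1
    epsilon: float = 6230.0
    conversion_path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("formation", "second_order_decay"):
            raise ValueError("mechanism must be 'formation' or 'second_order_decay'")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.times_s is None:
            if self.mechanism == "formation":
                self.times_s = np.linspace(0.0, 2e-6, 2001)
            else:
                self.times_s = np.linspace(0.0, 8.4e-5, 841)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("time grid must be strictly increasing")


def _bump(recipe: TraceRecipe) -> np.ndarray:
    t = recipe.times_s
    return (
        recipe.bump_amplitude
        * (1.0 - np.exp(-t / recipe.bump_rise_s))
        * np.exp(-t / recipe.bump_decay_s)
    )


def _apply_noise(values: np.ndarray, recipe: TraceRecipe) -> np.ndarray:
    if recipe.noise_fraction == 0:
        return values
    rng = np.random.default_rng(recipe.seed)
    return values * (1.0 + recipe.noise_fraction * rng.standard_normal(values.shape))


def gen_formation_trace(recipe: TraceRecipe) -> KineticTrace:
    """Pseudo-first-order radical formation trace.

    c_radical(t) = c_OH,0 (1 - exp(-k2 [scav] t)), with the scavenger
    depleted stoichiometrically, Beer-Lambert absorbance at the recipe's
    absorptivities, the electron bump added, and multiplicative noise.
    At a wavelength where scavenger and radical absorptivities are equal
    the noiseless post-bump trace is constant (isosbestic behavior).
    """
    if recipe.mechanism != "formation":
        raise ValueError("recipe mechanism must be 'formation'")
    if recipe.scavenger_conc <= 0 or recipe.k2 < 0 or recipe.c_oh0 < 0:
        raise ValueError("formation recipe requires scavenger_conc > 0 and k2, c_oh0 >= 0")
    if recipe.eps_scavenger < 0 or recipe.eps_radical < 0:
        raise ValueError("absorptivities must be >= 0")
    t = recipe.times_s
    k_obs = recipe.k2 * recipe.scavenger_conc
    c_rad = recipe.c_oh0 * (1.0 - np.exp(-k_obs * t))
    c_scav = np.clip(recipe.scavenger_conc - c_rad, 0.0, None)
    a = recipe.path_cm * (
        recipe.eps_scavenger * c_scav + recipe.eps_radical * c_rad
    ) + _bump(recipe)
    return KineticTrace(t, _apply_noise(a, recipe), recipe.wavelength_nm, recipe.path_cm)


def gen_decay_trace(recipe: TraceRecipe) -> KineticTrace:
    """Second-order radical decay trace.

    A(t) = A0 / (1 + s A0 t) with s = 2k / (eps * l_conv), so the
    reciprocal absorbance is exactly linear with slope s in the noiseless
    limit; the absorbance halves when s * A0 * t = 1.
    """
    if recipe.mechanism != "second_order_decay":
        raise ValueError("recipe mechanism must be 'second_order_decay'")
    if recipe.a0 <= 0 or recipe.epsilon <= 0 or recipe.conversion_path_cm <= 0:
        raise ValueError("decay recipe requires a0, epsilon, conversion path > 0")
    if recipe.rate_2k < 0:
        raise ValueError("rate_2k must be >= 0")
    t = recipe.times_s
    slope = recipe.rate_2k / (recipe.epsilon * recipe.conversion_path_cm)
    a = recipe.a0 / (1.0 + slope * recipe.a0 * t)
    return KineticTrace(t, _apply_noise(a, recipe), recipe.wavelength_nm, recipe.path_cm)


def _default_crocin_bands() -> list[GaussianBand]:
    # main-band amplitude None: solved so the total at 441 nm hits the anchor
    return [
        GaussianBand(441.0, math.nan, 78.0),
        GaussianBand(460.0, 3.0e4, 30.0),
        GaussianBand(333.0, 6.0e3, 40.0),
        GaussianBand(250.0, 3.0e4, 45.0),
    ]


def gen_crocin_like_spectrum(
    grid_nm: np.ndarray | None = None,
    bands: Sequence[GaussianBand] | None = None,
    anchor: tuple[float, float] | None = (441.0, 1.35e5),
) -> Spectrum:
    """Crocin-like molar absorptivity spectrum as a sum of Gaussian bands.

    Defaults: intense 441 nm band anchored to 1.35e5 M^-1 cm^-1, a 460 nm
    shoulder, weak 333 and 250 nm bands, negligible (<1% of peak)
    absorptivity beyond 550 nm.  A band with NaN amplitude has its
    amplitude solved so the summed spectrum matches the anchor.
    """
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    band_list = list(_default_crocin_bands() if bands is None else bands)
    free = [i for i, b in enumerate(band_list) if math.isnan(b.amplitude)]
    if free:
        if anchor is None or len(free) > 1:
            raise ValueError("exactly one NaN-amplitude band and an anchor are required")
        lam, target = anchor
        i = free[0]
        fixed = [b for j, b in enumerate(band_list) if j != i]
        others = _band_values(np.array([lam]), fixed)[0]
        b = band_list[i]
        sigma = b.fwhm_nm * _SIGMA_PER_FWHM
        shape = math.exp(-0.5 * ((lam - b.center_nm) / sigma) ** 2)
        band_list[i] = b._replace(amplitude=(target - others) / shape)
    values = _band_values(grid, band_list)
    if np.any(values < 0):
        raise ValueError("band amplitudes produce negative absorptivities")
    return Spectrum(grid, values, kind="molar_absorptivity", species="crocin")


def gen_product_like_spectrum(
    grid_nm: np.ndarray | None = None,
    eps_330: float = 0.25e5,
    eps_441: float = 0.11e5,
    eps_375: float | None = None,
) -> Spectrum:
    """Twice-oxidized-product absorptivity spectrum.

    Three Gaussian bands (330, 380, 441 nm) with amplitudes solved linearly
    so the spectrum takes the prescribed values at 330, 375 and 441 nm.
    ``eps_375`` defaults to the default crocin fixture's value at 375 nm,
    which makes 375 nm an exact isosbestic point of the pair.
    """
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    if eps_375 is None:
        eps_375 = gen_crocin_like_spectrum(np.array([374.0, 375.0, 376.0])).value_at(375.0)
    centers = np.array([330.0, 380.0, 441.0])
    fwhms = np.array([60.0, 70.0, 60.0])
    targets_at = np.array([330.0, 375.0, 441.0])
    targets = np.array([eps_330, eps_375, eps_441])
    sigma = fwhms * _SIGMA_PER_FWHM
    design = np.exp(
        -0.5 * ((targets_at[:, None] - centers[None, :]) / sigma[None, :]) ** 2
    )
    amps = np.linalg.solve(design, targets)
    if np.any(amps < 0):
        raise ValueError("product band targets produce a negative band amplitude")
    bands = [GaussianBand(c, a, f) for c, a, f in zip(centers, amps, fwhms)]
    values = _band_values(grid, bands)
    return Spectrum(grid, values, kind="molar_absorptivity", species="croc(-2H)")


def gen_radical_like_spectrum(
    grid_nm: np.ndarray | None = None,
    bleach_441: float = 18_200.0,
    gain_333: float = 3_000.0,
    eps_678: float = 6_230.0,
) -> Spectrum:
    """Oxidized-radical absorptivity: crocin minus a 375-510 nm depression
    plus a weak 333 nm gain and the characteristic 678 nm band.

    The depression is a smooth window vanishing at 375 and 510 nm, so those
    wavelengths remain isosbestic points with crocin up to the far tails of
    the weak added bands (<1% of the local absorptivity).
    """
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    croc = gen_crocin_like_spectrum(grid)
    inside = (grid >= 375.0) & (grid <= 510.0)
    window = np.zeros_like(grid)
    window[inside] = np.sin(math.pi * (grid[inside] - 375.0) / 135.0) ** 2
    # scale so the depression at 441 nm equals the requested bleach
    w441 = math.sin(math.pi * (441.0 - 375.0) / 135.0) ** 2
    values = croc.values - (bleach_441 / w441) * window
    values += _band_values(grid, [GaussianBand(333.0, gain_333, 40.0)])
    values += _band_values(grid, [GaussianBand(678.0, eps_678, 70.0)])
    if np.any(values < 0):
        raise ValueError("radical spectrum went negative; adjust band parameters")
    return Spectrum(grid, values, kind="molar_absorptivity", species="croc(-H) radical")


@dataclass
class SpectrumRecipe:
    """Recipe for a dose-indexed absorbance series (gamma irradiation).

    Two absorptivity components (parent + product) mixed by the linear
    consumption law c_parent = c0 - G*D (floored at zero), Beer-Lambert
    absorbance in a ``path_cm`` cell, multiplicative noise.  Doses must
    include 0; the default ladder extends past the parent-exhausting dose,
    as in the experiment.
    """

    eps_parent: Spectrum | None = None
    eps_product: Spectrum | None = None
    doses_gy: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 97.0, 145.0, 211.0)
    g: float = 4.0e-7  # mol/J consumption yield
    c0: float = 5.7e-5  # M
    path_cm: float = 0.1
    noise_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.doses_gy:
            raise ValueError("dose ladder must include 0")
        if self.g < 0 or self.c0 <= 0 or self.path_cm <= 0:
            raise ValueError("g >= 0 and c0, path_cm > 0 required")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.eps_parent is None:
            self.eps_parent = gen_crocin_like_spectrum()
        if self.eps_product is None:
            self.eps_product = gen_product_like_spectrum(self.eps_parent.wavelength_nm)


def gen_dose_series(recipe: SpectrumRecipe) -> dict[float, Spectrum]:
    """Dose-indexed absorbance spectra of the two-component mixture.

    Mass balance c_parent + c_product = c0 holds exactly at every dose
    before flooring; wherever the two component absorptivities are equal,
    all noiseless spectra agree (isosbestic points by construction).
    """
    parent, product = recipe.eps_parent, recipe.eps_product
    grid = parent.wavelength_nm
    if product.wavelength_nm.shape != grid.shape or not np.allclose(
        product.wavelength_nm, grid
    ):
        product = product.resample(grid)
    rng = np.random.default_rng(recipe.seed)
    out: dict[float, Spectrum] = {}
    for dose in sorted(recipe.doses_gy):
        consumed = min(recipe.g * dose, recipe.c0)
        c_parent = recipe.c0 - consumed
        a = recipe.path_cm * (parent.values * c_parent + product.values * consumed)
        if recipe.noise_fraction > 0:
            a = a * (1.0 + recipe.noise_fraction * rng.standard_normal(a.shape))
        out[float(dose)] = Spectrum(
            grid, a, kind="absorbance", path_cm=recipe.path_cm, species=f"dose {dose:g} Gy"
        )
    return out


@dataclass
class LineListRecipe:
    """Recipe for a synthetic electronic-transition line list.

    Each configuration carries ``lines_per_config`` transitions whose
    energies jitter around the given band centers; oscillator strengths are
    gamma-distributed.  A ``contamination_fraction`` of lines is marked
    spin-contaminated with <S^2> = ground * (1 + contamination_excess);
    clean lines stay within 10% of the ground-state value, below the usual
    20% screen.
    """

    n_configurations: int = 400
    lines_per_config: int = 10
    band_centers_ev: tuple[float, ...] = (2.8114, 3.7, 4.9)
    energy_jitter_ev: float = 0.12
    osc_strength_scale: float = 0.4
    ground_s2: float = 0.75
    contamination_fraction: float = 0.0
    contamination_excess: float = 0.5
    species: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination fraction must be in [0, 1]")
        if self.n_configurations <= 0 or self.lines_per_config <= 0:
            raise ValueError("need at least one configuration and one line")


def gen_linelist(recipe: LineListRecipe) -> LineEnsemble:
    """Synthetic line ensemble, deterministic from the recipe seed."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_configurations * recipe.lines_per_config
    centers = np.resize(np.asarray(recipe.band_centers_ev, dtype=float),
                        recipe.lines_per_config)
    energy = np.abs(
        np.tile(centers, recipe.n_configurations)
        + rng.normal(0.0, recipe.energy_jitter_ev, n)
    )
    osc = rng.gamma(shape=2.0, scale=recipe.osc_strength_scale, size=n)
    contaminated = rng.random(n) < recipe.contamination_fraction
    s2 = recipe.ground_s2 * (1.0 + 0.1 * rng.random(n))
    s2[contaminated] = recipe.ground_s2 * (1.0 + recipe.contamination_excess)
    lines = pd.DataFrame(
        {
            "config_index": np.repeat(np.arange(recipe.n_configurations),
                                      recipe.lines_per_config),
            "energy_ev": energy,
            "osc_strength": osc,
            "s2": s2,
        }
    )
    return LineEnsemble(
        lines,
        ground_s2=recipe.ground_s2,
        species=recipe.species,
        total_steps=recipe.n_configurations,
        burn_in=0,
        stride=1,
    )
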