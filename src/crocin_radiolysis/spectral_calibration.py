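"""Molar-absorptivity calibration algebra and dose-series deconvolution.

The transient and steady-state spectra are calibrated against the known
crocin molar absorptivity through the 1:1 stoichiometry established by the
isosbestic points: absorbance ratios at equal optical path translate
directly into absorptivity ratios.  A differential (transient-minus-parent)
spectrum added to the parent absorptivity spectrum gives the absolute
spectrum of the transient.  The dimer absorptivity follows from the ratio
of the early (radical) and late (dimer) bleaching amplitudes, since each
dimer consumes two radicals.  Finally, the gamma-dose series is unmixed
into the two Beer-Lambert components (remaining crocin + oxidation product)
under mass balance, yielding the product spectrum and the experimental
consumption yield G_exp.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "CalibrationResult",
    "IsosbesticReport",
    "DoseSeriesDeconvolution",
    "calibrate_by_ratio",
    "differential_to_absolute",
    "dimer_epsilon",
    "dimer_bleach_ratio",
    "find_isosbestic",
    "deconvolve_dose_series",
    "g_exp_from_bleach",
]

SPECTRUM_KINDS = ("absorbance", "molar_absorptivity", "differential", "intensity")


@dataclass
class Spectrum:
    """Wavelength-gridded optical data.

    ``kind`` is one of ``absorbance``, ``molar_absorptivity`` (values must
    be >= 0), ``differential`` (signed molar absorptivity difference) or
    ``intensity`` (arbitrary units, e.g. oscillator-strength density from a
    line-list convolution).
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"
    path_cm: float | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelength grid and values must be 1-D")
        if self.wavelength_nm.shape != self.values.shape:
            raise ValueError("wavelength grid and values must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if self.kind == "molar_absorptivity" and np.any(self.values < 0):
            raise ValueError("molar absorptivities must be >= 0 (use kind='differential')")

    def value_at(self, wavelength_nm: float) -> float:
        """Linear interpolation at one wavelength; extrapolation forbidden."""
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if not lo <= wavelength_nm <= hi:
            raise ValueError(f"{wavelength_nm} nm outside grid [{lo}, {hi}] nm")
        return float(np.interp(wavelength_nm, self.wavelength_nm, self.values))

    def resample(self, grid_nm: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid_nm``; extrapolation forbidden."""
        grid_nm = np.asarray(grid_nm, dtype=float)
        if grid_nm[0] < self.wavelength_nm[0] or grid_nm[-1] > self.wavelength_nm[-1]:
            raise ValueError("resampling grid extends beyond the spectrum range")
        return Spectrum(
            grid_nm,
            np.interp(grid_nm, self.wavelength_nm, self.values),
            kind=self.kind,
            path_cm=self.path_cm,
            species=self.species,
        )


@dataclass
class CalibrationResult:
    """Calibrated molar absorptivities of one species at named wavelengths."""

    species: str
    eps_m1cm1: dict[float, float]
    isosbestic_nm: tuple[float, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        for lam, eps in self.eps_m1cm1.items():
            if eps < 0:
                raise ValueError(f"negative absorptivity at {lam} nm")


def calibrate_by_ratio(eps_ref: float, a_ref: float, a_target: float) -> float:
    """Absorptivity of the target band from a same-path absorbance ratio.

    eps_target = eps_ref * A_target / A_ref, valid under 1:1 stoichiometry
    between the species carrying the reference and target bands (both
    absorbances measured at equal optical path).
    """
    if a_ref <= 0:
        raise ValueError("reference absorbance must be > 0")
    return eps_ref * a_target / a_ref


def differential_to_absolute(diff: Spectrum, ref: Spectrum) -> Spectrum:
    """Absolute absorptivity spectrum = reference + differential, pointwise.

    The differential spectrum is resampled onto the reference grid.  Small
    negative results (noise) are clipped to zero with a warning.
    """
    if ref.kind != "molar_absorptivity":
        raise ValueError("reference spectrum must be a molar absorptivity")
    if (
        diff.wavelength_nm[0] > ref.wavelength_nm[-1]
        or diff.wavelength_nm[-1] < ref.wavelength_nm[0]
    ):
        raise ValueError("differential and reference wavelength ranges are disjoint")
    if diff.wavelength_nm.shape == ref.wavelength_nm.shape and np.allclose(
        diff.wavelength_nm, ref.wavelength_nm
    ):
        diff_vals = diff.values
    else:
        lo = max(diff.wavelength_nm[0], ref.wavelength_nm[0])
        hi = min(diff.wavelength_nm[-1], ref.wavelength_nm[-1])
        keep = (ref.wavelength_nm >= lo) & (ref.wavelength_nm <= hi)
        ref = Spectrum(ref.wavelength_nm[keep], ref.values[keep], kind=ref.kind)
        diff_vals = np.interp(ref.wavelength_nm, diff.wavelength_nm, diff.values)
    values = ref.values + diff_vals
    if np.any(values < 0):
        warnings.warn(
            "negative absorptivities after adding the differential spectrum; clipped to 0",
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    return Spectrum(ref.wavelength_nm, values, kind="molar_absorptivity", species=diff.species)


def dimer_epsilon(eps_croc: float, eps_radical: float, ratio: float) -> float:
    """Dimer absorptivity from the late/early bleaching-amplitude ratio.

    Each dimer consumes two radicals, so its concentration is half the
    radical's and the bleach amplitudes satisfy

        (eps_c - 1/2 eps_d) / (eps_c - eps_r) = dA_end / dA_early

    solved here for eps_d = 2 [eps_c - ratio (eps_c - eps_r)].  A negative
    result is flagged as unphysical.
    """
    if eps_croc <= eps_radical:
        raise ValueError("requires a bleaching regime: eps_croc > eps_radical")
    if ratio <= 0:
        raise ValueError("bleach-amplitude ratio must be > 0")
    eps_d = 2.0 * (eps_croc - ratio * (eps_croc - eps_radical))
    if eps_d < 0:
        warnings.warn("negative dimer absorptivity: inputs are inconsistent", stacklevel=2)
    return eps_d


def dimer_bleach_ratio(eps_croc: float, eps_radical: float, eps_dimer: float) -> float:
    """Inverse of :func:`dimer_epsilon`: the bleach ratio a dimer spectrum implies."""
    if eps_croc <= eps_radical:
        raise ValueError("requires a bleaching regime: eps_croc > eps_radical")
    return (eps_croc - 0.5 * eps_dimer) / (eps_croc - eps_radical)


@dataclass
class IsosbesticReport:
    """Isosbestic wavelengths located in a family of spectra."""

    wavelengths_nm: list[float]
    degenerate: bool = False


def find_isosbestic(
    spectra: list[Spectrum],
    tolerance: float = 0.02,
) -> IsosbesticReport:
    """Wavelengths where a family of spectra (shared grid) coincide.

    The across-spectra spread (max - min per wavelength) is compared with
    ``tolerance`` x (global maximum spread); contiguous sub-threshold runs
    are merged to the spread-minimizing wavelength.  Identical spectra give
    a degenerate report (every wavelength would qualify).
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    grid = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if s.wavelength_nm.shape != grid.shape or not np.allclose(s.wavelength_nm, grid):
            raise ValueError("spectra must share a wavelength grid")
    values = np.vstack([s.values for s in spectra])
    spread = values.max(axis=0) - values.min(axis=0)
    global_max = float(spread.max())
    scale = float(np.max(np.abs(values))) or 1.0
    if global_max <= 1e-12 * scale:
        return IsosbesticReport([], degenerate=True)

    hits = spread < tolerance * global_max
    wavelengths: list[float] = []
    i = 0
    n = hits.size
    while i < n:
        if hits[i]:
            j = i
            while j + 1 < n and hits[j + 1]:
                j += 1
            k = i + int(np.argmin(spread[i : j + 1]))
            wavelengths.append(float(grid[k]))
            i = j + 1
        else:
            i += 1
    return IsosbesticReport(wavelengths)


@dataclass
class DoseSeriesDeconvolution:
    """Two-component unmixing of a dose-indexed absorbance series."""

    product_eps: Spectrum
    concentrations: pd.DataFrame  # columns: dose_gy, c_known, c_product, consumed
    g_exp: float  # mol/J, slope of consumed concentration vs dose
    n_iterations: int
    converged: bool
    flags: list[str] = field(default_factory=list)


def _series_matrix(
    series: Mapping[float, Spectrum], eps_known: Spectrum, path_cm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    doses = np.array(sorted(series), dtype=float)
    if doses[0] != 0.0:
        raise ValueError("dose series must include the zero-dose spectrum")
    grid = eps_known.wavelength_nm
    cols = []
    for d in doses:
        spec = series[d]
        if spec.kind != "absorbance":
            raise ValueError("dose-series spectra must be absorbances")
        cols.append(spec.resample(grid).values / path_cm)
    return doses, grid, np.column_stack(cols)  # shape (n_lambda, n_dose)


def deconvolve_dose_series(
    series: Mapping[float, Spectrum],
    eps_known: Spectrum,
    c0: float,
    path_cm: float,
    *,
    product_anchor: str | tuple[float, float] | None = "max_dose",
    g_dose_max_gy: float = 97.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DoseSeriesDeconvolution:
    """Unmix a dose series into remaining parent + product under mass balance.

    Model, per dose D and wavelength:  A/l = c_k(D) eps_k + c_p(D) eps_p
    with the mass balance c_k + c_p = c0 (one product molecule per consumed
    parent).  Solved by per-dose constrained linear least squares for the
    concentrations alternating with a pooled least-squares update of the
    product spectrum, until the spectrum changes by less than ``tol``
    (relative) or ``max_iter`` iterations.

    Mass balance and nonnegativity alone leave a one-parameter scale
    ambiguity (the product spectrum can be mixed with the parent spectrum
    while rescaling all product concentrations), so an anchor is required:

    - ``"max_dose"`` (default): the highest dose is taken as fully
      converted (c_p = c0) — valid when the series extends beyond the dose
      exhausting the parent, as in a gamma series run to saturation;
    - ``(wavelength_nm, eps_value)``: the product absorptivity is known at
      one wavelength (e.g. from an independent calibration);
    - ``None``: plain alternating least squares, flagged scale-indeterminate.

    ``g_exp`` is the through-origin slope of the consumed concentration vs
    dose over doses <= ``g_dose_max_gy`` (the range over which the
    two-component model, signalled by the isosbestic point, holds).
    """
    if c0 <= 0 or path_cm <= 0:
        raise ValueError("c0 and path_cm must be > 0")
    if eps_known.kind != "molar_absorptivity":
        raise ValueError("eps_known must be a molar absorptivity spectrum")
    doses, grid, d_mat = _series_matrix(series, eps_known, path_cm)
    eps_k = eps_known.values
    n_dose = doses.size
    flags: list[str] = []

    anchor_max = product_anchor == "max_dose"
    anchor_wl: tuple[float, float] | None = None
    if isinstance(product_anchor, tuple):
        anchor_wl = (float(product_anchor[0]), float(product_anchor[1]))
    elif product_anchor is None:
        flags.append("scale_indeterminate: no product anchor supplied")
    elif not anchor_max:
        raise ValueError(f"unknown product_anchor {product_anchor!r}")

    if anchor_max and n_dose >= 2:
        eps_p = np.clip(d_mat[:, -1] / c0, 0.0, None)
    else:
        eps_p = np.zeros_like(eps_k)

    c_known = np.full(n_dose, c0)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # per-dose constrained least squares for the parent concentration
        diff = eps_k - eps_p
        denom = float(diff @ diff)
        if denom <= 1e-12 * float(eps_k @ eps_k):
            flags.append("rank_deficient: product spectrum ~ parent spectrum")
            break
        c_known = np.clip((d_mat - c0 * eps_p[:, None]).T @ diff / denom, 0.0, c0)
        c_known[0] = c0  # zero dose: nothing consumed
        if anchor_max:
            c_known[-1] = 0.0  # anchor: parent exhausted at the top dose
        c_prod = c0 - c_known

        # pooled update of the product spectrum from doses with product present
        active = c_prod > 0
        if not np.any(active):
            flags.append("no_consumption: series shows no product formation")
            break
        resid = d_mat[:, active] - np.outer(eps_k, c_known[active])
        eps_p_new = resid @ c_prod[active] / float(c_prod[active] @ c_prod[active])
        n_clipped = int(np.sum(eps_p_new < 0))
        eps_p_new = np.clip(eps_p_new, 0.0, None)
        if n_clipped > 0.2 * eps_p_new.size:
            flags.append("negative_eps_clipped: >20% of product spectrum clipped to 0")

        if anchor_wl is not None:
            # project onto the anchor constraint along the mixing family
            lam, val = anchor_wl
            cur = float(np.interp(lam, grid, eps_p_new))
            ref = float(np.interp(lam, grid, eps_k))
            if abs(ref - cur) > 1e-12 * max(abs(ref), 1.0):
                gamma = (val - cur) / (ref - cur)
                eps_p_new = np.clip((1 - gamma) * eps_p_new + gamma * eps_k, 0.0, None)

        scale = float(np.max(np.abs(eps_p_new))) or 1.0
        delta = float(np.max(np.abs(eps_p_new - eps_p))) / scale
        eps_p = eps_p_new
        if delta < tol:
            converged = True
            break

    c_prod = c0 - c_known
    consumed = c0 - c_known
    table = pd.DataFrame(
        {"dose_gy": doses, "c_known": c_known, "c_product": c_prod, "consumed": consumed}
    )
    in_range = (doses > 0) & (doses <= g_dose_max_gy)
    if np.any(in_range):
        d_fit = doses[in_range]
        g_exp = float(consumed[in_range] @ d_fit / (d_fit @ d_fit))
    else:
        g_exp = math.nan
        flags.append("no_doses_in_linear_range")
    if anchor_max and np.isfinite(g_exp) and g_exp * doses[-1] < c0:
        flags.append("max_dose_anchor_suspect: top dose may not fully convert the parent")

    return DoseSeriesDeconvolution(
        product_eps=Spectrum(grid, eps_p, kind="molar_absorptivity", species="product"),
        concentrations=table,
        g_exp=g_exp,
        n_iterations=n_iter,
        converged=converged,
        flags=flags,
    )


def g_exp_from_bleach(delta_a: float, delta_eps: float, path_cm: float, dose_gy: float) -> float:
    """Experimental consumption yield (mol/J) from a bleaching amplitude.

    G = dA / (d_eps * l * D), with dA the absorbance decrease at the probe
    wavelength, d_eps the parent-minus-product differential absorptivity,
    l the cell path and D the dose.
    """
    if delta_eps <= 0 or path_cm <= 0 or dose_gy <= 0:
        raise ValueError("delta_eps, path_cm and dose_gy must be > 0")
    if delta_a < 0:
        raise ValueError("bleaching amplitude must be >= 0")
    return delta_a / (delta_eps * path_cm * dose_gy)
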