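# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data round trips do and do not
demonstrate about real measurements.

## Radiolytic yield scheme

Primary yields are stored in SI mol/J and printed in 10⁻⁷ mol J⁻¹; the
defaults are the standard water values at a scavenging factor of 10⁻⁷ s⁻¹
(e⁻_aq 2.8, H⁺ 2.8, H• 0.62, H₂ 0.47, OH• 2.8, H₂O₂ 0.73). Dose is
converted to concentration with the dilute-water convention 1 Gy ≙ 1 J/L;
every closed-form result in the package (e.g. [OH•] = 5.4×10⁻⁵ M at 97 Gy)
assumes it. Scheme yields:

* pulse, N₂O: every oxidizing equivalent consumes one crocin —
  G(e⁻_aq) + G(OH•) + G(H•); the dimer yield is half of that.
* gamma, N₂O: radical disproportionation halves the consumption while the
  accumulated H₂O₂ slowly oxidizes crocin too —
  ½(G_eaq + G_OH + G_H + 2 G_H₂O₂).
* gamma with Ag⁺: H atoms are diverted to silver, whose atoms regenerate
  crocin, and the remainder disproportionates — ½(G_eaq + G_OH − G_H).
  The ½ prefactor is required for the scheme value (2.5×10⁻⁷ mol J⁻¹) to
  follow from the primary yields; it is applied here explicitly.

Time-dependent spur chemistry and scavenging-capacity corrections to G are
out of scope.

## Kinetic fits

Both fits are the classical linearization "tests", by unweighted ordinary
least squares (no weighting scheme is part of the model being reproduced):

* Formation: ln|A∞ − A(t)| vs t, k_obs = −slope, k₂ = k_obs/[scavenger].
  A∞ defaults to the mean of the final 5% of samples. The fit window
  starts at 50 ns to exclude the hydrated-electron bump, and ends — within
  the window — at the first crossing of 90% conversion, because beyond
  that the plateau distance is comparable to the ±5% absorbance noise and
  the log transform would be noise-dominated. Before taking the log the
  plateau distance is smoothed with a short moving average (≤15 points):
  for an exponential this multiplies the signal by a constant, leaving the
  slope exactly unbiased, while shrinking the log-noise and its concavity
  bias by √k. Edge points of the smoothing kernel are discarded, and only
  the contiguous pre-cutoff stretch enters the regression so plateau noise
  cannot re-enter it. A nonlinear least-squares option
  (`method="nonlinear"`) is available but the linearized test is the
  default and the one used everywhere in the package's own analyses.
* Decay: 1/A vs t; the slope (s⁻¹) converts to concentration units as
  2k = slope × ε × l_conv. `conversion_path_cm` defaults to 1 cm — the
  convention under which the reported slope 0.6×10⁶ s⁻¹ and
  ε₆₇₈ = 6.23×10³ M⁻¹ cm⁻¹ reproduce 2k = 3.7×10⁹ M⁻¹ s⁻¹ directly —
  and is exposed as a parameter for the strict Beer–Lambert conversion
  with the actual cell path.

Fits flag (rather than raise on) non-positive rates, poor linearity
(R² < 0.9), and unreached plateaus (end rise rate above 10% of the initial
rise rate).

## Spectral calibration and deconvolution

Calibration algebra follows from 1:1 stoichiometry anchored by isosbestic
points: ε_target = ε_ref × A_target/A_ref at equal optical path;
radical spectrum = crocin spectrum + differential spectrum (small negative
results are clipped to zero with a warning, as noise can undershoot);
dimer absorptivity from (ε_c − ½ε_d)/(ε_c − ε_r) = ΔA_late/ΔA_early, since
each dimer consumes two radicals. Optical paths differ between experiments
(0.5 cm pulse cell, 1–2 mm steady-state cells), so the path is always an
explicit argument. Resampling between wavelength grids is linear
interpolation; extrapolation is forbidden.

The dose series A(λ, D)/l = c_croc ε_croc + c_prod ε_prod is unmixed under
the mass balance c_croc + c_prod = c₀ by alternating per-dose constrained
least squares (concentrations clipped to [0, c₀]) with a pooled update of
the product spectrum, iterated to a 10⁻⁸ relative change or 100
iterations. Mass balance and nonnegativity alone leave a one-parameter
family of exact solutions (the product spectrum can be mixed with the
parent while rescaling the product concentrations), so the decomposition
needs one anchor. The default treats the highest dose as fully converted —
the natural choice for a series run past the parent-exhausting dose, as
the gamma experiment was (211 Gy × 4×10⁻⁷ mol J⁻¹ > 5.7×10⁻⁵ M); a
post-hoc flag warns when the fitted yield suggests the top dose did not
exhaust the parent. Alternatively a known product absorptivity at one
wavelength can be supplied, or no anchor (flagged scale-indeterminate).
G_exp is the through-origin slope of consumed concentration vs dose over
doses ≤ 97 Gy, the range over which the persisting isosbestic point
certifies the two-component model; higher doses (secondary oxidation of
the product) are excluded from the slope, not modeled.

The isosbestic finder reports wavelengths where the across-spectra spread
falls below `tolerance` × (maximum spread), merging contiguous runs to the
spread-minimizing wavelength; identical spectra yield a degenerate report.

In recovery tests the concentration error is normalized by c₀ (the total
concentration scale) rather than by the per-dose product concentration,
which vanishes at small doses and would make a ratio meaningless.

## Spectrum synthesis from line lists

Each electronic transition contributes a Gaussian in the energy domain,
centered at its excitation energy, with area equal to its oscillator
strength (f is an integrated intensity, so area — not height — is the
conserved quantity) and a prescribed fwhm in eV: 0.70 eV for broadening
lines of single optimized structures, 0.50 eV for intense bands and weak
high-energy bands of a sampled simulation, 0.20 eV for weak low-energy
bands. Per-configuration sums are averaged over configurations (pooling
and averaging coincide when every configuration carries a full line list,
the case for the generated ensembles); the result is evaluated on a
200–900 nm grid at 1 nm. No Jacobian reweighting is applied beyond the
variable change — the spectrum is a function of energy sampled at the
grid's energies.

Spin screening discards lines whose ⟨S²⟩ exceeds the ground-state value by
more than the screening parameter, interpreted by default as a *relative*
excess (a "20%" screen keeps ⟨S²⟩ ≤ 1.2 × ground); an absolute mode is
available. Screening is idempotent and monotone in the parameter.

Mixing weights are probabilities summing to one. The sugar-driven model
gives monomer weights p_a = 1 − f/2, p_b = f/2 for a chain-encounter
fraction f (sugar encounters migrate to the nearest chain methyl): f = 1
is the no-sugar-influence limit (½, ½), f = ⅓ the sugar-driven (⅚, ⅙).
Independent radical pairing extends these binomially to dimer weights
(p_a², 2p_a p_b, p_b²).

## Monte-Carlo conformer engine

Moves: collective Gaussian "multi-stretch" displacement of all sites
(probability 0.8) and torsional moves about a uniformly chosen rotatable
bond (0.2), the torsional proposal being a uniform perturbation
(±0.35 rad) or a cis↔trans flip with equal probability — the proposal law
is an artifact choice, as is the stretch amplitude (0.015, tuned to ~50%
acceptance on the default surrogate at 295 K). Acceptance is Metropolis.
The random stream is split from the master seed into per-purpose
substreams (move selection, stretch, torsion, acceptance) so trajectories
are reproducible and stable against refactors of any single proposal.
Recording keeps every stride-th configuration after the burn-in
(production convention: 60,000 steps, 20,000 burn-in, stride 100 → 400
configurations; constrained conformer runs: 20,000 steps, stride 100 →
200). Freezing torsions disables torsional moves on those bonds; freezing
all of them yields the constrained, fixed-conformer runs. Temperature
defaults to 295 K; conformer searches use 1000 K. Parallel tempering is
deliberately not implemented.

The production energy surface (DFT at every step) is external by design.
The shipped surrogate — per-torsion double wells (trans minimum, cis
minimum offset by a configurable gap, default 0.07 eV, matching the
lowest single-cis isomerization free energy) plus harmonic site restraints
— exists to exercise both move types against analytic stationary
distributions; a two-state step potential provides the exact Boltzmann
target for sampler validation. Conformers are classified per isomerizable
bond by the sign of cos θ.

## Thermochemistry

Wertz correction: ΔG_corr = ΔG_pcm − ½(ΔG_gas − ΔH_gas) + k_B T, with
k_B T in eV at the record's temperature (per-particle equivalent of the
molar RT; the term cancels the PV convention in the gas-phase enthalpy).
Default temperature 295 K (22 °C). The redox deduction uses the
one-equivalent convention — a reaction free energy in eV equals a
potential shift in V — against E°(OH•/H₂O) = 2.0 V vs NHE, so the
−1.98 eV H-abstraction free energy places the crocin-model couple at
≈ 0 V vs NHE. The table of computed reaction free energies (H-abstraction,
dimerization, disproportionation intermediates and cyclic products,
complexation) ships as package data; singlet-diradical entries are marked
as lower bounds.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* the analysis relies on: an
exponential approach to plateau with rate k₂[croc] on top of a
hydrated-electron bump confined to the first ~50 ns (2 ns rise, 8 ns
decay — the electron lifetime under N₂O saturation is a few ns, and the
observed transient is over by 50 ns, which is also where the default fit
window starts); an exactly hyperbolic second-order decay; Gaussian-band
absorptivity fixtures with the 441 nm crocin band at 1.35×10⁵ M⁻¹ cm⁻¹,
the 460 nm shoulder, weak 333/250 nm bands and <1% absorptivity beyond
550 nm; a product spectrum pinned to 0.25×10⁵/0.11×10⁵ M⁻¹ cm⁻¹ at
330/441 nm and crossing crocin exactly at 375 nm; dose series obeying
exact mass balance with the consumption law c₀ − G·D floored at zero; and
line lists with a configurable fraction of spin-contaminated lines.
Noise is multiplicative Gaussian at 5% (a relative uncertainty).

Default problem sizes — 2001-point traces over 2 µs (formation) and
841 points over 84 µs (decay), seven doses from 0 to 211 Gy on a 1 nm
grid, 100-seed recovery ensembles, 2×10⁵-step two-state MC runs — were
chosen so every round trip is statistically decisive at these noise
levels while individual checks complete in seconds.

What passing round trips show: the fitting and unmixing code inverts its
own generative model without bias at the stated noise level. What they do
not show: robustness to structured instrument artifacts (streak-camera
shading, wavelength-dependent noise, baseline drift), to deviations from
strict two-component behavior below 97 Gy, to photodegradation during
gamma irradiation, or to errors in the assumed primary yields — none of
which the generators emulate. The >100 Gy secondary-oxidation regime is
excluded from the fitted dose range, not modeled.

## Known limitations

* The dose-series deconvolution requires a scale anchor (see above); with
  neither a saturating dose nor an independent product absorptivity the
  product spectrum is identified only up to a mixing parameter.
* The second-order conversion path and the pseudo-first-order plateau are
  conventions exposed as parameters; results quoted per the package
  defaults assume the 1 cm conversion path and last-5% plateau.
* The surrogate MC energy is not a chemical potential-energy surface; MC
  results validate the sampler, not crocin conformer populations.
* Line-list convolution assumes every configuration contributes the same
  number of lines when equating pooling with configuration averaging.
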