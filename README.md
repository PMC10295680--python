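# crocin-radiolysis

Analysis pipeline for the oxidation of crocin — the carotenoid diester that
gives saffron its color and much of its antioxidant capacity — by hydroxyl
radicals generated radiolytically in water. The package reimplements, as
tested, reusable code, the full chain of arithmetic that turns
pulse-radiolysis transients and gamma-irradiation dose series into reaction
rate constants, molar absorption coefficients of the transient species, and
radiolytic consumption yields, together with the simulation-side machinery
(line-list spectrum synthesis, Monte-Carlo conformer sampling,
thermochemical corrections) used to assign the oxidation mechanism.

It is written for radiation chemists and computational spectroscopists who
want the individual steps — G-value bookkeeping, kinetic linearizations,
isosbestic-anchored calibrations, two-component spectral deconvolution,
Gaussian line broadening with spin screening — as composable, unit-tested
functions rather than spreadsheet arithmetic.

## The model in brief

Water radiolysis deposits a known cocktail of primary species per joule,

    H2O ⇝ e⁻_aq (2.8), H⁺ (2.8), H• (0.62), H2 (0.47), OH• (2.8), H2O2 (0.73)

(yields in 10⁻⁷ mol J⁻¹). Under N₂O the hydrated electron converts to OH•,
so G(OH•) = G(e⁻_aq) + G(OH•) = 5.6×10⁻⁷ mol J⁻¹ and a 97 Gy pulse makes
[OH•] = 5.4×10⁻⁵ M. Crocin (croc) scavenges OH• by H-abstraction,

    croc + OH• → croc(−H)• + H2O,     k₂ from ln|A∞ − A(t)| vs t,

and the oxidized radical recombines second-order,

    2 croc(−H)• → (croc(−H))₂,        2k = slope(1/A vs t) × ε₆₇₈.

Absorptivity calibration rests on the 1:1 stoichiometry established by the
isosbestic points (375, 510 nm): ε ratios equal same-path absorbance
ratios; dimer absorptivity follows from the early/late bleach ratio because
each dimer consumes two radicals. The gamma dose series is unmixed into
remaining crocin + twice-oxidized product under mass balance, giving
G_exp(−croc) to compare with the reaction-scheme values ½(G_eaq + G_OH +
G_H + 2 G_H2O2) etc. On the simulation side, TDDFT line lists sampled
along MC trajectories are Gaussian-broadened in energy (area ∝ oscillator
strength), spin-contaminated lines screened, and species spectra mixed by
formation probabilities — equal (½, ½) or sugar-driven (⅚, ⅙) — with
binomial extension (p_a², 2p_a p_b, p_b²) to the radical dimers.

## Worked example

```python
from crocin_radiolysis import radiolysis_yields as ry
from crocin_radiolysis import kinetics, synthetic_data as syn

# OH radical burst of a 97 Gy pulse in N2O-saturated water
g_oh = ry.oh_yield()                          # 5.6e-07 mol/J
c_oh = ry.dose_to_concentration(97.0, g_oh)   # 5.43e-05 M

# simulate a noisy 678 nm formation trace at 0.13 mM crocin and re-fit it
trace = syn.gen_formation_trace(syn.TraceRecipe(seed=1))
fit = kinetics.fit_pseudo_first_order(trace, scavenger_conc=1.3e-4)
print(f"k_obs = {fit.k_obs:.3g} s^-1, k2 = {fit.k2:.3g} M^-1 s^-1, R2 = {fit.r_squared:.3f}")
```

prints

```
k_obs = 4.44e+06 s^-1, k2 = 3.42e+10 M^-1 s^-1, R2 = 0.994
```

i.e. the pseudo-first-order constant k_obs = k₂[croc] and the recovered
bimolecular rate constant k₂ ≈ 3.4×10¹⁰ M⁻¹ s⁻¹ for OH• + crocin — a
diffusion-controlled scavenging rate. The end-to-end runs are available as
`crocin_radiolysis.pipeline.run_pulse_analysis` /
`run_gamma_analysis` (or `crocin-radiolysis run-all --seed 1 --out results/`),
which also report ε₆₇₈(radical) ≈ 6230, ε₄₄₁(radical) ≈ 1.17×10⁵,
ε₄₄₁(dimer) ≈ 1.84×10⁵ M⁻¹ cm⁻¹, 2k ≈ 3.7×10⁹ M⁻¹ s⁻¹ and
G_exp(−croc)(γ) ≈ 4.0×10⁻⁷ mol J⁻¹.

## Package layout

| module                 | contents |
|------------------------|----------|
| `radiolysis_yields`    | primary G-values, dose↔concentration, e⁻_aq dosimetry, scheme yields |
| `kinetics`             | trace container, pseudo-first-order and second-order fits, order discrimination |
| `spectral_calibration` | spectra, ratio/differential/dimer calibrations, isosbestic finder, dose-series deconvolution |
| `spectrum_synthesis`   | line ensembles, subsampling, spin screening, Gaussian convolution, probability mixing |
| `mc_conformers`        | Metropolis engine (multi-stretch + torsional moves), cis–trans enumeration, surrogate surface |
| `thermochem`           | Wertz correction, redox deduction, tabulated reaction free energies |
| `synthetic_data`       | generators for traces, spectra, dose series and line lists |
| `pipeline` / `cli`     | end-to-end runs with manifests; `crocin-radiolysis` console entry point |

See `docs/methods.md` for the scientific and numerical choices in detail.
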