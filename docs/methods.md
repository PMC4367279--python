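# Methods

This note documents the models behind each analysis stage, the defaults
and their units, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Aggregation kinetics

ThT fluorescence traces are modelled as a Boltzmann sigmoid
`y(t) = y0 + a/(1 + exp(-(t - Ti)/τ))` with time in hours and signal in
relative fluorescence units (RFU). Derived quantities are the elongation
rate `1/τ` (h⁻¹), the plateau `y0 + a` (RFU), and the lag time
`Ti − 2τ` (h) — the intercept of the inflection-point tangent with the
baseline. The baseline `y0` is fitted rather than forced to zero, because
real ThT traces carry a nonzero dye background.

Fitting is trust-region nonlinear least squares with bounds (`τ > 0`,
`a ≥ 0`). Initialisation: `y0 = min(y)`, `a = max(y) − min(y)`, `Ti` at
the half-rise time, `τ` = (25–75% rise span)/2.2; up to five seeded,
jittered restarts follow a convergence failure. Flat traces (no
amplitude) fail with an explicit error rather than returning a degenerate
fit. Standard errors come from the covariance of the fit; R² is
`1 − SS_res/SS_tot` on the fitted window.

Some aggregating peptides show a small, reversible early fluorescence
transient before the main growth phase. It is deliberately not modelled
with an extra term — its molecular origin is unsettled and a transient
term would trade off against the baseline. Instead `fit_tht` takes a fit
window that excludes it; the generator emits a warning when a synthetic
transient encroaches on the inflection region.

Mechanistic models (nucleation-elongation moment closures, secondary
nucleation) are out of scope; the sigmoid is purely descriptive.

## CD unmixing

A far-UV CD spectrum is modelled as `y = Σ_s f_s B_s` with fractions on
the probability simplex (`f ≥ 0`, `Σf = 1`). The solver enumerates active
sets and solves the equality-constrained normal equations on each support
(KKT system), returning the exact constrained optimum — for ≤ 4–6 classes
this is both exact and fast, avoiding penalty terms or renormalisation
hacks. The fit quality statistic is the normalized spectral fit S.D.,
defined here as RMS(residual)/RMS(spectrum); fits with S.D. > 0.07 are
flagged poor. When several basis sets are tried, the candidate with the
lowest S.D. wins; exact ties resolve to input order and are noted.

The packaged `default4` basis is synthetic: sums of Gaussian bands at
conventional far-UV positions (helix: +65·G(192,9) − 22·G(208,11) −
20·G(222,12); sheet: +32·G(196,9) − 14·G(218,11); coil: −20·G(198,10) +
2·G(220,25); turn: +8·G(205,14) − 3·G(225,18); amplitudes in arbitrary
mdeg-like units, G(center nm, FWHM nm)). It is linearly independent and
spans 190–260 nm at 0.5 nm. It exists for forward modelling and
round-trip validation; quantitating real spectra requires a measured
reference basis. Basis spectra are linearly interpolated onto the data
grid; extrapolation outside the basis range is a hard error.

## Tryptophan emission deconvolution

Components are unit-height Gaussians in wavelength,
`exp(−4 ln2 (λ−c)²/w²)` with FWHM `w`; the area of a unit-height profile
is `w·sqrt(π/(4 ln2))`. Parameterising in nm (not wavenumber) matches how
the emission data are presented; the choice is documented because
photophysics conventions differ. Default components: 359 nm / 60 nm
(solvent-exposed, listed first) and 327 nm / 40 nm (buried).

Fixed-component fits solve a non-negative linear least-squares problem
for the areas only — the design matrix holds unit-area profiles so the
coefficients are areas directly; fractions are area shares. An all-zero
spectrum yields a flagged degenerate result instead of undefined
fractions.

The free two-Gaussian fit refines centers, widths and areas with bounds
(width ∈ [5, 200] nm, areas ≥ 0) from several deterministic starting
points. Because a single emission band can be split arbitrarily between
two coincident Gaussians, the two-component model is retained only when
it improves the residual substantially over a single-Gaussian reference
fit (RSS reduced by >1%); otherwise the single-Gaussian solution is
returned with a zero-area second component. This makes the
single-component case well defined instead of returning an arbitrary
split.

## REDOR dephasing and distance inversion

The frequency-selective experiment is modelled as ideal two-spin REDOR:
perfect selective recoupling of the chosen ¹³C–¹⁵N pair, all other
couplings suppressed, no pulse imperfections or relaxation. The dipolar
coupling is `d = K_CN/r³` with
`K_CN = (μ0/4π)·γ_C·γ_N·ħ/(2π) = 3063.5 Hz·Å³`, recomputed from CODATA
gyromagnetic ratios and frozen as a package constant (3.8 Å → 55.8 Hz).
A π-pulse train applied every half rotor cycle gives a total dephasing
time `n/(2·ν_MAS)`.

Powder-averaged dephasing depends only on `λ = d·t`:
`ΔS/S₀ = 1 − (√2π/4)·J_{1/4}(√2λ)·J_{−1/4}(√2λ)`. The closed form is
validated in the test suite against an independent numeric powder average
of `cos(ΔΦ)` with accumulated phase `ΔΦ = 4√2·λ·sinβ·cosβ·sinα` on a
512-point midpoint (α, β) grid with sinβ weighting (agreement ≤ 1e−3 over
λ ∈ [0, 5]; grid-doubling shows convergence). ΔS/S₀ is monotone in λ on
[0, ~0.8], the operating regime of a ~3–4 Å pair at ms dephasing times.

When the monitored region contains signals from non-recoupled sites, the
observed dephasing is diluted: `S/S₀(t) = 1 − f·ΔS/S₀(d·t)`. The factor
`f` is computed from a shift table as (target entries in the monitored
window)/(all entries in the window), assuming equal per-carbon intensity;
for the medin carbonyl region (167–183 ppm, four carbons, one of them the
recoupled Asp25 Cγ) this gives 0.25.

Distance inversion is a grid search (default 2–8 Å, 0.01 Å) minimising
the residual sum of squares. The bounding interval collects the extreme
grid distances whose model curves stay inside the noise band at every
observation. The band half-width is `z·σ` with `z` the Šidák-corrected
simultaneous normal quantile at 95% for the number of points (z ≈ 2.83
for 11 points): a literal ±1σ-at-every-point band would be empty almost
surely (the max of n i.i.d. |N(0,σ)| deviations exceeds σ with
probability 1 − 0.683ⁿ), whereas the calibrated band covers the true
distance with ≈95% probability by construction, verified by a seeded
coverage simulation in the tests. With σ = 0 the band degenerates to the
point estimate. If the band reaches the top of the grid the interval is
flagged unbounded above — no dephasing was detected beyond noise.
Intra- versus intermolecular origin of a contact is outside what the
measurement can decide.

## DARR simulation and shift-based classification

Time-domain signals are synthesised on a 512×512 grid (configurable) over
a 0–200 ppm window in both dimensions. Each carbon contributes an FID at
its own frequency in t₂, modulated in t₁ by its own frequency and by the
frequencies of its directly bonded carbons only — long-range couplings
are neglected, so the cross-peak pattern is the bond topology. Bonds
through heteroatoms (Met S; His, Trp, Arg ring N) do not couple carbons
and are omitted. User-supplied extra pairs inject specific long-range
cross-peaks (e.g. a Trp–Ile contact). Mixing-time dependence and
polarisation-transfer dynamics are not modelled.

Exponential decay sets a Lorentzian FWHM of 0.8 ppm by default — chosen
to resemble broad fibril lines while keeping backbone peaks resolvable;
no measured value is available, and it is configurable. Processing is
hypercomplex (States-style) absorption-mode: one absorption vector per
distinct frequency, outer products accumulated per modulation. Magnitude
processing was rejected because its dispersive ridges produced
crossing-artifact maxima up to ~0.4 of the global maximum on realistic
shift tables.

Peak picking takes 3×3 local maxima above a fractional threshold
(default 0.05) and refines positions by parabolic interpolation of the
inverse intensity, which is exact for an isolated absorption Lorentzian;
in practice off-grid centers are recovered to ≪0.1 grid spacing.
Symmetric partners are annotated. Peak-list comparison uses greedy
nearest-neighbour matching within a ppm tolerance, processed in order of
increasing distance for determinism.

Shift prediction assigns C′/Cα/Cβ from per-class reference means and
gives side-chain carbons beyond Cβ random-coil values regardless of
class. The coil table holds random-coil reference shifts; helix and sheet
means derive from it via the canonical secondary-shift offsets (helix:
C′ +1.9, Cα +2.6, Cβ −0.6 ppm; sheet: C′ −1.9, Cα −1.4, Cβ +2.2 ppm),
with the sheet rows for Ala, Asp and Lys set to the directly tabulated
literature values used as the fibril benchmark. The sign convention
helix Cα > coil Cα > sheet Cα holds for every residue and is asserted in
the tests. Classification picks the class with the lowest RMS deviation
over the observed atoms (at least Cα and Cβ required) and returns none
when the best class still deviates by more than a threshold (default
2.0 ppm RMS) — the unassignable case, typical of turn residues.

## Synthetic data

All generators are pure functions of (parameters, seed), using
`numpy.random.default_rng`. Noise is additive Gaussian everywhere; real
instrument noise structure (baseline drift, wavelength-dependent
variance, t₁ noise) is not emulated, so passing round-trip tests
demonstrates correctness of the estimators under the stated noise model,
not robustness to every instrumental artifact.

Defaults mirror the study conditions of the medin system: ThT sigmoids
sampled every 0.25 h over 0–50 h with plateau ≈716 RFU, rate ≈1.28 h⁻¹;
emission series on a 300–400 nm grid with the 359/60 and 327/40
components and a logistic fraction trajectory; CD series ending at
65% sheet / 35% coil; dephasing curves at 2–12 ms with correction factor
0.25 and σ = 0.05; the hairpin generator segments a sequence into
coil/sheet/turn/sheet spans (turn residues take coil shift values — no
separate turn shift statistics are embedded) with optional per-atom
Gaussian jitter. Generated dephasing ratios are clipped to the container's
plausibility band [−0.2, 1.2].

## Degenerate inputs and tie-breaks

- Flat kinetic traces and flat spectra: explicit fit-failure errors.
- Zero emission spectra: flagged degenerate deconvolution, no fractions.
- CD best-fit ties: first candidate in input order, tie noted.
- All-ones dephasing curves: interval unbounded above, flagged.
- Unknown atoms in shift tables: skipped with a logged count; unknown
  residues: hard error naming the position.
- Readers reject duplicate (residue, atom) keys, non-monotonic axes, and
  traces with fewer than 5 usable rows; non-numeric rows are dropped with
  their indices reported.

## Problem sizes

Default analyses run in milliseconds to seconds on one core: 512×512
spectrum synthesis is a handful of outer products and FFT-sized
operations; the REDOR oracle uses a 512² orientation grid; coverage and
noise-perturbation properties use 100 seeded replicates.
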