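# fibrilstack

Analysis stack for biophysical and solid-state NMR studies of amyloid
self-assembly, built around the data types produced when characterising a
fibril-forming peptide such as medin, the 50-residue protein of aortic
medial amyloid. The package covers five measurement modalities end to end
— from raw trace/spectrum files to fitted physical parameters — plus
seeded synthetic-data generators for every stage, so each analysis can be
validated by round-trip parameter recovery.

## What it computes

**Aggregation kinetics (`fibrilstack.tht`).** Thioflavin-T fluorescence
time courses are fitted with the Boltzmann sigmoid

    y(t) = y0 + a / (1 + exp(-(t - Ti)/τ))

giving the elongation rate 1/τ, the plateau y0 + a, and the lag time
Ti − 2τ. An optional fit window excludes the early reversible fluorescence
transient some aggregating peptides show.

**CD secondary structure (`fibrilstack.cd`).** Far-UV CD spectra are
unmixed as convex combinations of per-class basis spectra (helix, sheet,
turn, coil) by exact simplex-constrained least squares; across candidate
basis sets the fit with the lowest normalized spectral fit S.D.
(RMS residual / RMS signal) is selected, flagged when S.D. > 0.07.

**Tryptophan fluorescence (`fibrilstack.trp`).** Emission spectra are
deconvolved into Gaussian components — for medin a solvent-exposed
359 nm / 60 nm-FWHM band and a buried 327 nm / 40 nm band — either with
fixed centers/widths (areas are the only variables) or with all parameters
free. Component area fractions tracked over time report on the assembly
pathway.

**REDOR distances (`fibrilstack.redor`).** Frequency-selective REDOR
dephasing of an isolated ¹³C–¹⁵N pair is modelled by the universal curve
ΔS/S₀(λ) = 1 − (√2π/4)·J_{1/4}(√2λ)·J_{−1/4}(√2λ) with λ = (K_CN/r³)·t,
verified against a numeric powder average. Observed S/S₀ curves are
inverted to a distance with a noise-band bounding interval, including the
multi-site overlap correction factor for crowded spectral regions
(0.25 for the medin carbonyl region: one recoupled carbon among four).

**DARR spectra (`fibrilstack.darr`).** 2D ¹³C–¹³C correlation spectra are
simulated from chemical-shift tables by time-domain synthesis (512×512,
directly bonded spins only) and absorption-mode 2D Fourier transformation;
peaks are picked with sub-grid interpolation, matched against experimental
peak lists, and residues are classified as helix/sheet/coil from their
C′/Cα/Cβ shifts against reference means.

**Synthetic data (`fibrilstack.synth`).** Seeded generators emulate every
input modality with known ground truth.

## Worked example

```python
import numpy as np
from fibrilstack.synth import gen_tht, gen_dephasing
from fibrilstack.tht import fit_tht
from fibrilstack.redor import fit_distance, overlap_correction_factor
from fibrilstack.datasets import medin_shift_table

# ThT kinetics with an early reversible transient, fitted past it
trace = gen_tht(y0=12.0, a=716.07, t_inflection=28.5625, tau=1/1.28,
                hump=(8.0, 4.0, 60.0), sigma=7.0, seed=42)
fit = fit_tht(trace, fit_window=(15.0, None), seed=42)
print(f"rate = {fit.rate:.3f} h^-1, plateau = {fit.plateau:.1f} RFU, "
      f"lag = {fit.lag:.1f} h, R^2 = {fit.r_squared:.4f}")

# REDOR: invert a noisy dephasing curve to a C-N distance
f = overlap_correction_factor(medin_shift_table())   # 0.25
curve = gen_dephasing(3.8, f, np.arange(2.0, 12.1, 1.0), sigma=0.02, seed=42)
dist = fit_distance(curve, f)
print(f"r_hat = {dist.r_hat:.2f} A, "
      f"interval [{dist.r_lower:.2f}, {dist.r_upper:.2f}] A")
```

prints

```
rate = 1.295 h^-1, plateau = 728.1 RFU, lag = 27.0 h, R^2 = 0.9996
r_hat = 3.76 A, interval [3.55, 4.25] A
```

The fitted rate and plateau recover the generating parameters (1.28 h⁻¹,
728 RFU including baseline) despite the transient and 1% noise; the
27-hour lag is the inflection time minus twice the time constant. The
REDOR inversion recovers the generating 3.8 Å distance within the noise,
with the bounding interval giving the range of distances whose dephasing
curves stay inside the noise band — a salt-bridge-compatible contact.

A command-line interface mirrors the library:

```
fibrilstack synth tht --out work/ --seed 7
fibrilstack tht-fit --input work/trace.csv --window 15: --out fit.json
fibrilstack darr-sim --shifts shifts.tsv --out spec.txt --peaklist peaks.tsv
```

Every run writes a JSON manifest with the resolved options, input digests,
seed and package version.

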