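# Methods

This note documents the models, numerical choices and limitations behind
`nanoxrf`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model

A raster nano-XRF scan records, per pixel, an energy-dispersive spectrum
plus telemetry: real (dwell) time, live time, dead-time fraction and a diode
reading proportional to the incident flux.  The expected net counts of an
element line in one pixel are

    N_e = Yield_e · m_e · t_live · (Φ/Φ₀)

with `Yield_e` the absolute sensitivity in counts s⁻¹ ag⁻¹, `m_e` the
element mass inside the beam footprint (weight fraction × areal mass ×
beam area), and `Φ/Φ₀` the relative incident flux.  The Compton scatter
intensity is proportional to the total illuminated areal mass, which is what
makes it usable as an internal thickness/density monitor.

## Spectral model and fitting

Within the fitted region of interest the spectrum is a linear combination of

* one unit-area Gaussian per element line group, centred at the Kα (Lα for
  Pb) energy with detector width σ(E) = √(noise² + (2.355)²·F·ε·E)/2.355
  (noise 100 eV FWHM, Fano factor F = 0.114, ε = 3.85 eV/pair);
* a Legendre polynomial continuum (default order 4, configurable);
* Gaussian Compton (width scale 3×) and Rayleigh peaks.

Because centres and widths are fixed by the energy calibration, the model is
linear in its amplitudes.  Fitting is weighted least squares with weights
1/max(counts, 1), amplitudes bounded ≥ 0 (unconstrained solve first, BVLS
fallback when an amplitude goes negative), and 1σ uncertainties from the
covariance of the weighted normal equations.  On 200 Poisson replicates of a
fixed truth the reported σ matches the empirical scatter within a few
percent (see `tests/test_spectral.py`).  Kβ lines are folded into the
end-to-end yield calibration rather than fitted separately: calibration and
quantification share one line model, so group-ratio errors cancel.  Escape
and pile-up sum peaks are not modelled.

Line groups are effectively single lines here; on real detectors with escape
peaks and Kβ interference the simplified model would leave structured
residuals that this package does not capture.

## Segmentation

Cell and nucleus masks come from the smoothed Zn Kα map (Gaussian σ = 2 px):

1. the resin level is the median of the 2-px border frame (the cell is
   assumed inside the field of view);
2. a foreground candidate is everything above resin + max(3σ_resin, 5% of
   the 99th percentile);
3. the cytoplasm plateau is the histogram mode of the candidate eroded by
   the smoothing radius (mode, not median, so the bright nucleus and its
   blur halo do not bias it);
4. the cell boundary is the half-height midpoint between resin level and
   plateau — for a blurred step this sits at the true edge;
5. the nucleus is the upper multi-Otsu class inside the cell, accepted only
   if its mean exceeds the remaining cell by a contrast factor (default 2);
   a uniform cell therefore yields an empty nucleus mask and the set algebra
   `cytoplasm = cell − nucleus` degrades gracefully.

On simulated phantoms this recovers cell masks with Dice ≈ 0.96–0.99 and
nucleus masks with Dice ≈ 0.93–0.97.  Manual masks (TIFF/PNG, nonzero =
member) bypass all of this.  Pixel convention: row-major, 0-based, masks
share the scan grid.

## Quantification chain

1. **Conventional normalization**: `I ← I/(1−DT) · k̄_ref/k̄_self` applied
   identically to net, background, Compton and Rayleigh intensities.  The
   diode reading carries the absorber transmission, so normalizing the
   standard scan to the reference cluster's diode automatically converts
   yields to the no-absorber sample condition.
2. **Self-absorption of the thick standard**:
   `A_corr = (1−e^(−χφd))/(χφd)`, `χ = μ0/sinα + μ1/sinβ` — the standard
   fundamental-parameter form, with χφd a dimensionless optical depth and
   the correct thin-sample limit A_corr → 1.
3. **Yields**: `Yield = I_norm/(A_corr · m_ag · t_real)` per certified
   element, with relative σ from counting and certified uncertainty in
   quadrature.  A calibration line below 3σ significance on the standard
   scan (at the simulated statistics this is typically Ni and Pb, whose
   certified values are 0.045 and 0.063 mg/kg) is flagged
   `calibration_limited`: Gaussian propagation is meaningless for a <3σ
   anchor, and quantification marks such elements as below detection rather
   than reporting a pseudo-calibrated value.
4. **LOD**: `LOD = 3·√I_B/I_N · c / A_corr`, rescaled by √(t_ref/t_target).
   The factor 3 is configurable; only the √I_B form reproduces the 100×
   sensitivity gain of a 10⁴× longer cluster live time.
5. **Compton renormalization** (optional, default in the pipeline): net
   intensities × (C_ref/N_ref)/(C_self/N_self), i.e. per-area normalization
   precedes the Compton ratio.  This removes a pure thickness/density
   scaling exactly in expectation.
6. **Conversions**: m = I_norm/(Yield·t̄_px); weight fraction
   w = m/(ρ·N_pix·A_beam·T); molarity w·ρ/M (mol/L); areal w·ρ·T.  The
   identities are asserted to 1e-9 relative in the tests.  Thin-section
   (2 µm) sample self-absorption is neglected, as the yields+geometry route
   implies; A_corr for the sample side can be enabled by passing the
   sample's own χφd through `absorption_correction` if ever needed.
7. **Uncertainties**: relative variances of independent multiplicative
   factors add in quadrature; the counting σ of a net area is the fit σ
   (fallback √(N+2B)).

Display units follow magnitude: ≥0.1% → w%, ≥1 ppm → ppm, else ppb, with
below-LOD values retained but flagged.

## Statistics

Regression is over individual cluster values, not time-point means (with the
unequal 3/3/2 design the two disagree); a means-based option exists for
sensitivity analysis.  The 95% CI uses the t distribution with n−2 df.
"const." is assigned when r² < 0.05 and the CI spans zero — the grading of
trends is otherwise the slope sign.  ANOVA is the classical one-way F
(scipy); Kruskal–Wallis is the tie-corrected H with asymptotic χ² p and an
exact-permutation option for N ≤ 9.  Normality grades come from the
correlation of the P–P plot (Blom plotting positions (i−3/8)/(n+1/4) by
default, Hazen optional): +++ for r ≥ 0.99, ++ for r ≥ 0.95, else +.  The
thresholds are this package's own quantification of a visual grading.  No
multiple-testing correction by default (a Benjamini–Hochberg option
exists).  At the 3/3/2 design the ANOVA type-I error at α = 0.05 measured
over 10⁴ null simulations stays within [0.03, 0.08] (tested).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: 2 µm Spurr-resin sections of
density 1.13 g/cm³, 64 × 54 nm beam at 17 keV, 300 ms dwell, 90°/15°
geometry; a bovine-liver standard pellet of 13.1 mg/cm² scanned 10 × 10 µm²
at 200 nm step and 500 ms dwell behind a 12.5%-transmission absorber (a
square 50 × 50 grid; the printed point count of the original scan, 2550, is
not a square grid and is not forced); Poisson counting noise; lognormal
per-pixel diode drift (1% RSD — only relative variation matters since
intensities are diode-normalized); non-paralyzable dead time
DT = Rτ/(1+Rτ) with τ = 3 µs, giving ≈11–12% on the standard and ≈2% on
cells; Compton intensity 2.53·10⁷ counts s⁻¹ per g/cm² of illuminated mass,
chosen so a reference-scale cell cluster (~2·10⁴ px) accumulates a Compton
intensity of order 10⁷ counts; section-to-section thickness variation as a
per-dataset lognormal factor of 15% RSD (per-pixel variation optional).
Ground-truth sensitivities rise with Z from 2 (P) to 100 (Sr) counts s⁻¹
ag⁻¹, which puts the per-element counting regimes (majors ~10⁵ counts per
cluster, traces ~10–10³) in realistic proportion.  Phantom compositions are
the measured study-condition means for control, 1 h and 2 h nucleus and
cytoplasm, with ~10% lognormal cell-to-cell variability.

Deliberate simplifications, and hence what passing tests do *not* show about
real data: single effective Gaussians per line group (no Kβ/escape/sum
peaks); a quadratic-in-energy continuum that lies inside the quartic family
the fitter uses, so closure tests probe the quantification chain rather than
continuum-model mismatch; no secondary fluorescence or enhancement; no
radiation damage; no resin/cryoprotectant contamination chemistry; and a
parametric cross-section model (smooth photoelectric power law +
Klein–Nishina incoherent + parametric coherent term, no absorption edges)
shared between simulator and quantifier — absolute A_corr values are
therefore model-consistent, not database-accurate.  Seeding: each dataset
draws its arrays in a fixed documented order from one counter-based Philox
generator, so identical spec + seed is bit-identical.

## Numerical choices and degenerate inputs

Bounded solves use BVLS with tol 1e-12; a non-converged pixel is flagged in
the batch quality mask, never silently dropped, and a non-converged single
fit returns NaN areas with `converged=False`.  Empty ROIs, empty masks,
constant maps, containment violations, zero/negative Compton intensities and
missing diode telemetry raise errors naming the offending quantity.
All-identical groups return F = 0, p = 1 (and H = 0) rather than erroring.
Nucleus lobes sharing one cytoplasm are treated as independent nucleus
masks.

## Problem sizes

The bundled experiments use 100 × 100 px phantoms (cell ≈ 1 900 px) for
closure, 50 × 50 standard scans, 40–64 px grids for unit tests, 500
simulations for CI coverage and 10⁴ for the type-I error — sizes chosen so
the whole suite and the acceptance script each complete in about a minute
while keeping counting regimes realistic.

## Known limitations

Per-pixel batch fitting is a Python loop over bounded solves (~1.7 ms/px);
very large maps would want a vectorised or multiprocess route.  The
automated segmentation assumes one cell per field of view with a resin
border frame; multi-cell instance segmentation is out of scope.  Yield
calibration requires every quantified element to be certified and
significant in the standard; there is no cross-element yield interpolation.
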