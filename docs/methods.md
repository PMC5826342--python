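# Methods

## The measurement model

The FLEA assay reports a cell's extracellular phosphatase activity as the
fluorescence of the ELFA precipitate it deposited during a fixed incubation.
On a two-channel field image the pipeline (i) segments cells on the
chlorophyll-autofluorescence channel, (ii) measures each cell's projected
area, major-axis length and mean ELFA gray (`MGrey`) together with a
per-field background gray (`BgMGrey`), and (iii) converts to relative
fluorescence units with

    F_ELFA = Area · (MGrey − BgMGrey) / (T_exp · F_cal).

Assumptions: the ELFA signal is linear in exposure time; background is
spatially uniform within a field (estimated once per field, not per cell
neighbourhood — configurable only in the statistic, median vs mean); negative
net gray is a background fluctuation, clamped to zero and counted for QC. The
formula's output is declared to *be* per-hour under the assay's fixed 3-h
incubation; an optional `normalize_by_incubation` divides by incubation time
for cross-protocol use, off by default so the printed formula is reproduced
verbatim. The FU→fmol conversion (0.1 fmol FU⁻¹) is an empirical constant
carried as configuration, not re-derived. How `F_cal` is determined is
outside the model; it is opaque acquisition metadata (default 1), and the
dimensional mismatch between μm²·gray·ms⁻¹ and "FU cell⁻¹ h⁻¹" is carried,
not resolved.

Cell volume uses the only ellipsoid determinable from length plus projected
area: a prolate spheroid with circular cross-section, `W = 4·Area/(π·L)`,
`V = (π/6)·L·W²`. If the derived width exceeds the supplied length the axes
are swapped with a warning.

Growth rate is `μ = (ln N_f − ln N_i)/(t_f − t_i)` over a window free of
dilution events; the default window spans the second to third dilution
(first sample strictly after, last strictly before). Density comes from
chlorophyll through a monotone conversion curve; the default is linear
through the origin, on which μ provably does not depend (the slope cancels
in the log ratio — asserted numerically in the tests). Endpoint estimation
is the default; a regression-over-window option exists because whether the
original protocol used single samples or a fit is unknowable from the
description.

## Segmentation

The study demarcated cells manually; automating it is a deliberate
substitution, validated against synthetic ground truth (precision = recall
= 1 on noise-free fields). Default scheme: Otsu threshold on the chlorophyll
channel, 8-connected components, objects below 2 μm area-equivalent diameter
removed (the sample filters retain nothing smaller), border-touching objects
excluded. A fixed absolute threshold is available for images where Otsu is
inappropriate (e.g. empty fields are detected by the flat-image guard
instead). Touching-cell splitting is out of scope; the simulated cultures
are unicellular and fields sparse by construction.

## What the synthetic generator emulates — and what it does not

`synthetic_data` stands in for the undeposited microscope slides. Cells are
prolate spheroids rendered as non-overlapping filled ellipses (uniform
length and aspect-ratio ranges, uniform orientation), placed by rejection
sampling with a bounded retry budget; crowding is an explicit error, never a
silent overlap. Per-cell activity is a zero-inflated lognormal. On the ELFA
channel each cell's mask receives a *dithered* integer gray pattern whose
sum is `round(FU·T_exp·F_cal/px²)`, so inverting the F_ELFA equation on the
painted pixels reproduces the ground-truth activity to about 10⁻⁵ FU —
noise-free fields are therefore an exact oracle for the full pipeline, while
the rasters stay genuine 16-bit integers (saturation raises, it never
clips). Optional acquisition noise is Poisson shot noise plus Gaussian read
noise, both off by default; parameter sets that would drive a raster
negative are rejected rather than clipped.

Defaults declared (not inferred from any protocol description): pixel size
0.11 μm/px, ELFA exposure 500 ms, F_cal 1, backgrounds 50 (chl) / 100
(ELFA) gray, cell foreground 3000 gray. The generator does **not** simulate
optics (PSF, defocus, vignetting), touching or out-of-focus cells, mixed
species, or stray bacterial ELFA precipitates. Passing tests therefore
demonstrate correctness of the measurement chain, not robustness to real
microscopy artefacts — on real slides segmentation quality must be judged
separately.

### Treatment calibration

The six default treatments encode the study conditions: inorganic (I) or
organic (O) phosphorus at 858 / 16 / 10 μmol L⁻¹. Activity targets: I3 and
O3 population medians 0.4 and 1.6 FU (0.04 / 0.16 fmol cell⁻¹ h⁻¹), O2:I2
ratio 10; P-replete cultures nearly inactive (I1 median 0.01 FU with 60%
zero cells; O1 median 0.05 FU with 80% zeros). `activity_median_FU` is the
*population* median when fewer than half the cells are inactive — the
lognormal component's median is back-solved from the mixture quantile so the
pipeline recovers the target exactly in expectation — and the active-cell
median otherwise (the population median is then 0 by construction).
Lognormal sigmas (0.6–0.9 in natural log) were chosen once so each
treatment's histogram spans a few geometric classes, matching the qualitative
shapes described for the frequency distributions. Cell sizes: length 5.0–6.8
μm (P-replete, mean volume ≈ 27 μm³) and 6.0–8.0 μm (P-depleted, ≈ 45 μm³),
aspect ratio 1.8–2.2.

Growth series: exponential between `n_dilutions` evenly spaced dilutions
that reset chlorophyll to its target (10 μg L⁻¹ depleted, 50 replete);
factors below 1 (declining cultures) mean no dilution is applied.
Observation noise is multiplicative lognormal with unit mean at the stated
CV.

## Distributions and statistics

Activity histograms use geometric class bounds, base 0.02 FU and ratio 2 by
default — reproducing the class bounds named in the source material (0.02,
0.32, 0.64, ≈1.3, ≈5.1 FU; the 1.26/1.28 and 5.1/5.12 discrepancies are
rounding). Two classes sit outside the progression: the *zero class* (F_ELFA
exactly 0 after clamping — "no activity" is distinct from "low activity")
and an underflow class for 0 < FU ≤ base. Bins are half-open `(eₖ, eₖ₊₁]`;
percentages are relative to total cell count and must sum to 100 (checked to
10⁻⁹). Replicate distributions are averaged per class (mean ± SD), the
figure-style summary.

Treatment comparisons: three-way ANOVA (species × medium × P concentration,
df 1/1/2 for main effects, 1/2/2/2 for interactions) on
log(x+1)-transformed responses via statsmodels OLS + `anova_lm` (type II;
the balanced design makes the SS types coincide), post hoc Tukey HSD with
the studentized-range convention and no extra multiplicity layer. The
natural log is used; the transform base affects neither df, p-values of the
balanced F-tests' null behaviour, nor Tukey groupings. The null simulation
draws responses as `expm1(Normal)` so the transformed scale is exactly
normal, making the nominal 5% type-I rate an exact benchmark. Quantiles use
the linear-interpolation convention (NumPy default).

## Numerical choices and problem sizes

Oracle/recovery checks run on 30 fields × 5 cells (oracle equivalence) and
30 fields × 12 cells ≈ 360 cells per treatment (median recovery), matching
the per-variant cell counts of the emulated study; the null-calibration
simulation uses 1000 replicate designs. The oracle tolerance (2% per cell)
is dominated by the half-gray rounding of the painted mask sum; in practice
recovery is ~10⁻⁴ relative. Seeds propagate through
`numpy.random.default_rng`: a slide seed spawns per-field seeds, so any
field is reproducible in isolation.

## Known limitations

- Per-field (not per-cell-neighbourhood) background; fields with strong
  illumination gradients would bias MGrey − BgMGrey.
- No watershed splitting: touching cells on real images merge into one
  object.
- The fmol conversion is a single constant from an external calibration; no
  uncertainty is propagated through it.
- Volume assumes a circular cross-section; flattened (oblate) cells are
  misestimated.
- The growth estimator trusts the dilution log; unrecorded dilutions inside
  a window silently bias μ downward only if they are absent from the series
  metadata (recorded ones raise).
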