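# Methods

This note records the models implemented in `shearpoint`, the defaults
and why they were chosen, and what the synthetic benchmark does and does
not establish about real data.

## Chamber model

The chamber is treated as an ideal 1-D lubrication film: wall shear
stress between plates separated by gap *h* is τ = 6µQ/(h²w), and the
tapered width w(x) = 6µQ / (h² τ(x)) with τ(x) = τ₁ + (τ₂ − τ₁)x/L is the
unique profile that produces a linear shear ramp. Entrance effects,
side-wall drag and gasket compliance are ignored; the computed τ is the
*theoretical* level at each axial position, which is also how
measurements are mapped to shear in the analysis. All internal units are
CGS (cm, poise, dyn·cm⁻², cm³/s); config files may declare lengths in
m/mm/µm, viscosity in Pa·s or flow in ml/min and are converted at load.

Two presets are provided:

| preset | gasket h | τ range (dyn·cm⁻²) | µ (poise) | Q (cm³/s) | L (cm) |
|---|---|---|---|---|---|
| `HUVEC_CHAMBER` | 0.8 mm | 2 → 60 | 0.01 | 0.5 | 7 |
| `HDLEC_CHAMBER` | 1.6 mm | 0.5 → 20 | 0.01 | 0.5 | 7 |

The gasket heights and shear ranges are the experimentally meaningful
constraints; flow rate, viscosity and channel length are not uniquely
determined by them, so the presets are *range-matched*, not
geometry-matched: µ = 0.01 P is a standard value for aqueous culture
medium near 37 °C, and Q and L were fixed once at values giving a
plausible slide-sized footprint (inlet width 2.3 cm). Since τ(x) is
specified directly by its endpoints, every downstream result depends
only on the range, not on the particular Q/µ/L triple.

The cylindrical-vessel estimator τ = 8µV/D is exact for fully developed
Poiseuille flow. With µ = 0.09 P, V = 7.1 cm/s, D = 4.1 mm it gives
12.5 dyn·cm⁻² (3 s.f.); with µ = 0.06 P it evaluates to 8.31, slightly
below the commonly quoted 8.4 for the same inputs — the formula's value
is reported as computed, not adjusted.

## Synthetic monolayer generator

The generator emulates confocal fields of a confluent endothelial
monolayer under flow, with per-cell ground truth, so that segmentation,
morphometry and set-point estimation can be validated end to end.

**Biphasic response model.** A `ResponseModel` defines an optimal shear
range by its centre and half-width. Inside one half-width of the optimum
the response is fully "optimal"; outside, a Gaussian shoulder of the
same width interpolates toward the far-from-optimum level. Two readouts
are driven by the same weight: the target mean folded nucleus angle
(aligned level, default 20°, relaxing to the misaligned level, default
45° = random) and the transcription-factor nuclear fraction (default
0.7 at optimum, 0.3 baseline, a Smad-like peaked response; an NF-κB-like
response is the same object read with the "min" convention). An optional
`misaligned_mean_angle_high_deg` > 45 models perpendicular orientation at
very high shear; the default model is symmetric.

**Orientation sampling.** Signed orientations live on the 180°-periodic
axial circle and are drawn from a wrapped normal centred on the flow
axis (or on 90° when the target mean exceeds 45°). The dispersion σ is
found by numerically inverting the folded-mean function
m(σ) = E|X|, X ~ WN(0, σ) on (−90°, 90°], tabulated by quadrature, so
that the sampled population's mean folded angle equals the model target
exactly. `angle_concentration` divides into σ: 1 reproduces the target,
0 yields exactly uniform orientations (mean 45°); σ ≥ 150° is treated as
uniform (the wrapped normal is uniform to < 10⁻⁶ there).

**Geometry.** Nuclei are ellipses with semi-axes ~N(8, 0.5) × N(5, 0.4) µm
(clipped, major axis enforced), placed on a jittered square grid with a
25 µm minimum centroid spacing so masks never merge; an image too small
for the requested count raises rather than truncating. Default pixel
size 0.65 µm (a typical 20× confocal scale) and a 20 µm border margin.
The cytoplasm is an annulus: the nucleus ellipse grown by 6 µm. These
values stand in for unavailable acquisition metadata and are fixed, not
fitted.

**Rendering.** Channel 1 is the filled nucleus at constant amplitude;
channel 2 splits a fixed per-cell total intensity between nucleus and
annulus in proportion TF : (1 − TF), each spread uniformly. Both
channels get a Gaussian PSF (σ = 0.8 µm), constant background (100
counts) and additive Gaussian read noise (σ = 5 counts), then uint16
quantisation. The true per-cell TF is deterministic given local shear;
variability enters through optics and noise. Blur conserves integrated
signal away from borders (verified to 2 %), and default gains cannot
saturate; saturation under user-raised gains is counted and warned.

**What the generator does not emulate:** cell-to-cell biological
variability of TF at fixed shear, junction-touching and overlapping
nuclei, uneven illumination, autofluorescence, stress-fibre channels and
3-D structure. Passing the recovery tests therefore demonstrates the
correctness of the measurement chain under its stated assumptions, not
robustness to every imaging artefact of a real microscope.

## Segmentation

Nucleus masks follow the standard recipe: min–max normalisation (making
the result invariant to detector gain), CLAHE (clip 0.01, kernel 1/8 of
the image), a global threshold on the equalised image (Otsu by default,
an absolute quantile as option), 8-connected components, and an area
filter (default 25–400 µm², generous bounds around plausible endothelial
nuclei). Touching-nucleus splitting is deliberately off by default; the
generator enforces separation and real chambers at confluence mostly
show separated nuclei after size filtering.

Because the assay has no membrane stain, the whole-cell region is a
modelling choice. Default: each nucleus claims all pixels within 6 µm
(matching the generator's annulus), contested pixels going to the
nearest nucleus — an exact watershed-style partition computed on the
Euclidean distance transform, so regions of neighbouring cells tile
their union with no double assignment. Alternative: Otsu threshold of
the transcription-factor channel, foreground assigned to the nearest
nucleus within 18 µm. Neither is privileged as "the" historical method;
both are exposed and carried in provenance.

## Morphometry

Orientation comes from the second central moments of the binary nucleus
mask: θ = ½·atan2(2µ₁₁, µ₂₀ − µ₀₂), folded to [0°, 90°]. Regions with
fewer than 5 pixels, or with relative eigenvalue degeneracy below 10⁻³
(circular masks), return NaN and are flagged out of averages rather than
contributing arbitrary angles. Hard-edged rasterisation biases moment
orientation by up to ~1° depending on pixel phase; rendered (blurred)
nuclei measure with ~0.8° median error.

TF subtracts a background estimate before integrating. The ratio itself
contains no background term, but without subtraction any camera offset
bounds TF away from 0 and 1; the default estimate is the modal intensity
outside all cell regions (the mode is exact for integer images), and
`background=0` gives the literal un-subtracted ratio. Negative residuals
are clipped at zero; a non-positive whole-cell sum flags the cell.

Line-profile AUC is the trapezoidal integral of the background-subtracted,
zero-clipped profile over distance; both total (intensity·µm) and per-µm
means are available since either normalisation is defensible for
cross-section comparisons.

## Response curves and the set point

Cells are binned by shear (default 15 equal-width bins over the chamber
range). The statistical unit is the image: per-image means are averaged
within bins and the SEM is across images, reflecting that fields of
view, not cells, are independent; pooled-cell mode is available.

Smoothing is LOWESS — tri-cube weighted local linear regression over the
nearest ⌈frac·n⌉ points (default frac 0.5) with Cleveland's bisquare
robustness reweighting (default 3 iterations). The implementation is
in-package; its non-robust path agrees with the statsmodels reference to
~10⁻¹⁵, and its robust path correctly suppresses an outlier *at the
outlier's own abscissa*, which the delegated routine did not. For
**set-point estimation** the pipeline smooths with 0 robustness
iterations: each bin is already an average of ~100 cells, so large
residuals are structural lack-of-fit (curvature at the chamber ends),
and bisquare reweighting was observed to reject genuinely informative
edge bins and shift the optimum; robust iterations remain the default
for display smoothing, where resistance to a corrupted bin is the point.

The set point is the extremum of the smoothed curve (min for
orientation and NF-κB TF, max for Smad TF), refined by a three-point
parabolic vertex when interior — bins are ~4 dyn·cm⁻² wide and the true
optimum rarely sits on a centre. The optimal range is the maximal
contiguous run of bins containing the optimum whose smoothed value lies
≥ criterion_fraction (default 0.8) of the way from baseline to optimum;
the criterion is this package's operational definition (the phenomenon
is usually described only as a range), and both the fraction and the
baseline (a supplied no-flow value, else the worst smoothed bin) are
parameters. Location estimates are invariant to affine rescaling of the
response. A monotone curve returns its boundary bin with a flag instead
of failing. No multiple-testing correction is applied across the three
readouts; each ANOVA is reported per readout.

## Numerical and testing choices

- Seeds: a single top-level seed; per-image and per-stage streams are
  derived via `SeedSequence([seed, index])`, kept below 2³¹.
- Degenerate inputs: blank images segment to zero labels; images with
  zero detected cells are excluded from a run with a log notice; empty
  shear bins are dropped; all-empty binning is an error.
- ANOVA delegates to `scipy.stats.f_oneway` with explicit degrees of
  freedom and a NaN flag for the zero-variance/equal-means case.
- Benchmark sizes: recovery tests use 16 positions × 100 cells per
  chamber (≈ 570 px fields); the uniform-orientation benchmark uses 25
  fields × 400 cells (10⁴ nuclei). These sizes give sampling error well
  below the asserted tolerances (SEM of a folded-uniform mean at
  n = 10⁴ is ≈ 0.26°) while keeping the whole suite fast.
- Set-point recovery across seeds lands within ~1–2 dyn·cm⁻² of the
  generated optimum; a small rightward bias (~+1) is expected because
  the response curve is asymmetric around the optimum (the misaligned
  plateau is wider on the high-shear side).

## Known limitations

- The chamber model is lubrication-ideal; near the narrow outlet the
  width approaches the gap and the 1-D approximation degrades — real
  devices deviate most exactly where shear is highest.
- Whole-cell regions are geometric surrogates; absolute TF values
  depend on that choice even though within-experiment comparisons do
  not.
- The estimator reports a boundary flag, not an extrapolated optimum,
  when the optimum lies outside the scanned shear range.
- Orientation is nucleus-based; cell-body alignment can differ from
  nuclear alignment in principle.
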