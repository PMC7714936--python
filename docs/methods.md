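# Methods

This note documents the measurement models implemented in `clearquant`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical decisions taken where the underlying
procedure was ambiguous.

## Transparency

The measurement assumes the specimen acts as a contrast attenuator for a
periodic background pattern: a square-wave grating is photographed in
focus through and beside the brain, and the Michelson contrast
`C = (I_max − I_min)/(I_max + I_min)` is estimated from the *mean*
intensities of a light/dark ROI pair (not per-pixel extrema — ROI means
average out noise and grating imperfections).  Transparency is the
contrast ratio `t = C_brain / C_ctrl`.

Properties worth keeping in mind:

* `t` is invariant to multiplicative gain but **not** to an additive
  intensity offset: stray light or a camera pedestal depresses both
  contrasts and biases `t` toward the ratio of degraded contrasts.  The
  CLI prints a reminder; dark-frame subtraction is the user's job.  This
  behaviour is covered by a test.
* `t > 1` can occur through noise when the brain is essentially invisible.
  Values are reported unclamped with a warning flag, preserving
  measurement fidelity for downstream statistics.
* Thickness normalization is the linear form `t_norm = t · h / h_max`,
  with `h` the medulla height of the freshly fixed brain and `h_max` the
  maximum over the specimens of one pipeline run.  The linear form is
  implemented exactly as defined even though a Beer–Lambert style
  exponential normalization would be more physical; note it *down-weights*
  thin brains.  `h_max` is cohort-relative, so it is recorded in every
  output row and in the run manifest — results from different runs are
  comparable only when `h_max` matches.
* ROI pairs are recommended (not required) to have equal areas; only the
  label set {a, b, c, d} and in-bounds placement are enforced.

## Retained size

`R = D_post / D_pre` from one matched landmark pair per specimen, computed
in micrometres so pre and post images may differ in magnification (the
annotation schema accepts a per-image `pixel_size_um_post` override).
Landmark correspondence is the annotator's responsibility, mirroring the
manual landmark matching of the underlying protocol; sub-pixel coordinates
are accepted.  `R` is not capped at 1 — some media swell tissue.

## Bead-PSF model

Profiles are fitted with an intensity model

```
model(x) = a + b · shape(x),
shape    = normalize( Gauss(mu, sigma) ⊗ tophat(width = bead diameter, centre e) )
```

where `normalize` scales the convolved shape to unit maximum.  This
"peak-shape" composition keeps `a` interpretable as the luminance offset
and makes the peak value exactly `a + b`.  A literal composition — first
add the offset into the Gaussian, convolve, then rescale by `b/max` — is
available behind `model_profile(..., literal=True)` for comparison; it
distorts the offset term and is not used by the fitting pipeline.

The FWHM is extracted from the Gaussian component alone,
`FWHM = 2·sqrt(2 ln 2)·sigma ≈ 2.3548·sigma`: the top-hat term removes the
broadening contributed by the bead's physical 200 nm diameter, which is
*not* part of the instrument response.  Fitting with bead diameter 0 on
200 nm-bead data overestimates sigma by roughly 10% at
sigma ≈ 0.12 um; the correction reduces that bias by more than an order of
magnitude (tested).

Numerical choices:

* **Identifiability.** With a symmetric top-hat the model depends on `mu`
  and `e` only through `mu + e`; both are kept as fit parameters (the
  top-hat centre is part of the model's parameterization), but `e` is
  initialized at the profile maximum and bounded within ±2 initial sigma
  of it so the optimizer cannot wander along the degenerate ridge.  Only
  `sigma` is interpreted physically.
* **Discretization.** The convolution is a midpoint-rule sum over the
  top-hat support sampled 10× finer than the profile spacing (the 200 nm
  bead can be narrower than a voxel), evaluated directly at the requested
  positions; the unit-maximum normalization is located on a fine grid that
  explicitly includes the analytic peak position.  Below one fine-grid
  step the top-hat degenerates to a delta and the model reduces
  analytically to the plain Gaussian.
* **Initialization.** Offset = profile minimum; amplitude = range; centre
  = maximum sample; sigma = naive half-max crossing width / 2.3548,
  floored at half the sample spacing and capped at the profile span.
  Bounds: amplitude > 0, centre within the sampled range,
  sigma ∈ (0, span].
* **Degenerate input.** A flat profile returns `converged = False` with
  zero residual; optimizer failure is reported through the flag, never an
  exception.
* **Tie-breaks.** Best slice: lowest z among equal mean intensities.
  Maximum-intensity voxel: first in (z, y, x) lexicographic order.
* **Bead isolation.** Connected components above `threshold_rel` × stack
  maximum (default 0.5); any pair of centroids closer than
  `min_separation_um` (default 2 um) is discarded *pairwise* — a
  contaminated neighbour biases sigma upward, so neither partner is kept.
* Profile half-widths default to 0.6 um laterally and 1.5 um axially,
  roughly ±5 sigma at the expected widths; beads whose windows are clipped
  by the stack edge are excluded with a logged count.

Per bead, lateral FWHM is the mean of the x- and y-profile FWHMs taken in
the best (highest-mean) slice, and axial FWHM is the z-profile FWHM
through the global maximum voxel.  Terminology note: some instrument
conventions label the in-plane average "axial" and the vertical in-plane
direction "sagittal"; this package consistently uses *lateral* (in-plane,
x/y averaged) and *axial* (along z).  Summaries are means with SEM
(sample s.d./√n; reported as 0 when n = 1).

## Group statistics

Two-sided Mann–Whitney–Wilcoxon with mid-ranks.  The p-value is exact —
full permutation null via the count recursion — whenever the combined
sample size is ≤ 16 and there are no ties, which covers the 7–9 specimen
groups these experiments produce; otherwise the normal approximation with
tie and continuity correction (scipy) is used, and the method is recorded
in the output.  Quartiles use linear interpolation between order
statistics (numpy's default, the "inclusive" convention) and whiskers sit
at the most extreme points within 1.5·IQR — plotting-tool defaults vary,
so the convention is fixed here for reproducibility.  No multiple-testing
correction is applied; the number of tests performed is printed so users
can apply their own.

## Synthetic generators

The generators are constructed so the analysis is their exact inverse:

* **Grating scenes.** Square-wave grating (period 40 px, contrast 0.5
  around a mid-gray level of 120 on an 8-bit scale) with an elliptical
  brain whose interior multiplies the grating's AC component by `tau` —
  pure contrast attenuation, no blur, so the measured `t` equals `tau`
  analytically.  Pixels are quantized to the integer camera grid before
  Gaussian read noise is added; recovery is exact to machine precision
  whenever `tau · amplitude` is integral (true for the tau values used in
  the validation suites), and within ~0.5% otherwise.  The default
  geometry mimics a large fly brain: 300 × 150 px semi-axes at 5 um/px ≈
  3000 × 1500 um fresh size; the pre-clearing image shows the ellipse at
  `1/scale` times the post size so the auto-landmarks return `R = scale`
  exactly.  ROIs are auto-placed on whole light/dark bars (no edge
  pixels).  Default noise 2.4 ≈ SNR 50 at mid-gray; landmark jitter 0.5 px
  emulates pixel-resolution manual annotation.
* **Bead stacks.** Five 200 nm beads per stack, anisotropic Gaussian PSF
  (sigma_lat 0.12 um, sigma_ax 0.35 um), voxel pitch (0.1, 0.05, 0.05) um
  — 2× lateral oversampling of a confocal pixel — and Poisson shot noise
  with peak counts `snr²` plus small Gaussian read noise (default SNR 30).
  The default bead footprint is a **separable box** (a 200 nm rect along
  each axis) rather than a solid sphere: the central line cut of a
  sphere ⊗ Gaussian is broadened by a dome-shaped effective kernel that no
  1-D rect matches, which would put a ~4–5% floor under the lateral sigma
  error and make the generator useless as a sharp oracle for the top-hat
  model.  With the box footprint the 1-D Gaussian ⊗ top-hat model is exact
  along each axis (up to voxel integration, < 1%), so end-to-end recovery
  validates the fitting code rather than a modelling mismatch.  A
  `bead_shape="sphere"` mode (oversampled voxel-integrated rendering) is
  provided for robustness experiments.
* **Cohorts.** Per-treatment normal distributions of `tau` and `scale`
  (clipped to valid ranges) and a uniform 0.8–1.0 brain-size factor so
  medulla heights differ across specimens; output is a directory of TIFFs
  and annotation JSONs the CLI consumes unchanged, plus a ground-truth
  table.  All randomness derives from the stated seed; identical seeds
  give byte-identical outputs.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: light scattering and blur (attenuation is purely
multiplicative), depth-dependent attenuation and spherical aberration,
uneven illumination and camera pedestal, tracheal-tube shadows and other
structured artifacts, landmark mis-correspondence between pre and post
images (only isotropic jitter), and bead Brownian motion or aggregation.
Real-data error budgets are therefore expected to be dominated by exactly
the effects the contracts warn about (offset sensitivity, annotation
quality), not by the estimator numerics validated here.

## Problem sizes

The validation suites use scenes of 448 × 768 px, bead stacks of
48 × 192 × 192 voxels with 5 beads, 100-scene Monte-Carlo transparency
studies, 200-replicate landmark-jitter studies and 500-replicate power
simulations — sizes chosen so the full suite runs in well under a minute
apiece on a single CPU while keeping the Monte-Carlo standard errors an
order of magnitude below the tolerances being asserted.

## Known limitations

* No flat-field or dark-frame correction is applied; bit depth is taken
  from the file dtype, and physical pixel size must be supplied (TIFF
  resolution tags are only cross-checked with a warning).
* The PSF fit is 1-D per axis; no 3-D model, no depth-dependent aberration
  term, no deconvolution.
* Automatic ROI/landmark placement exists only for synthetic scenes; real
  images require manual annotation, as in the protocol the package
  implements.
* The annotation format carries a free-text landmark label (e.g. to note
  that a tear or tracheal tube was used on a very clear brain) but no
  quality score.
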