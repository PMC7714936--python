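# clearquant

Objective quantification of optical tissue-clearing performance from
standard microscope images, developed around the kind of benchmarking done
for insect (fly) brains cleared in media with tunable refractive index
(Rapiclear, SeeDB2, TDE, methyl salicylate/Permount).

Clearing protocols are usually compared by eye.  `clearquant` instead
measures, per specimen:

* **Transparency** — the brain is photographed over a square-wave
  background grating before and after clearing.  From the mean intensities
  of light/dark ROI pairs beside (`a`, `b`) and through (`c`, `d`) the
  brain, the Michelson contrast

  $$C = \frac{I_{max} - I_{min}}{I_{max} + I_{min}}$$

  gives the transparency $t = C_{brain} / C_{ctrl}$ — the fraction of
  grating contrast surviving the whole tissue thickness (1 = perfectly
  clear).  Because thicker brains attenuate more, $t$ is normalized by the
  medulla height $h$ of the freshly fixed brain relative to the cohort
  maximum: $t_{norm} = t \cdot h / h_{max}$.

* **Retained size** — the distance $D$ between matched anatomical
  landmarks measured pre and post clearing gives
  $R = D_{post} / D_{pre}$; $R < 1$ is shrinkage.

* **PSF width** — sub-resolution (200 nm) fluorescent beads are imaged as
  confocal z-stacks; 1-D intensity profiles through each isolated bead are
  fitted with a Gaussian convolved with a 200 nm top-hat (accounting for
  the bead's near-resolvable size), and the resolution is reported as
  $\mathrm{FWHM} = 2\sqrt{2\ln 2}\,\sigma$ of the Gaussian component,
  laterally (mean of x/y) and axially (z), with SEM across beads.

Treatments are compared with two-sided Mann–Whitney–Wilcoxon tests (exact
permutation p-values for the small group sizes typical of these studies)
and median/quartile summaries.

A synthetic-scene generator produces grating scenes, bead stacks and whole
annotated cohorts with exact ground truth, so every stage of the pipeline
is verifiable without any raw imaging data.

## Worked example

```python
import numpy as np
from clearquant import (SceneGroundTruth, generate_grating_scene,
                        compute_transparency, compute_retained_size,
                        BeadSceneGroundTruth, generate_bead_stack,
                        analyze_bead_stack, summarize_fwhm)

# a synthetic specimen with known attenuation (tau=0.6) and shrinkage (scale=0.85)
scene = generate_grating_scene(
    SceneGroundTruth(tau=0.6, scale=0.85, noise_sigma=2.4, seed=42))
pair = scene.as_pair(specimen_id="#45", treatment="Rapiclear1.52_E")
res = compute_transparency(pair, h_max_um=1500.0)
shrink = compute_retained_size(pair)
print(f"t = {res.t:.4f}, t_norm = {res.t_norm:.4f}, R = {shrink.r:.4f}")

# bead-PSF estimation (true sigma_lat = 0.12 um, sigma_ax = 0.35 um, SNR 30)
stack, _ = generate_bead_stack(BeadSceneGroundTruth(seed=42))
fits, _ = analyze_bead_stack(stack)
s = summarize_fwhm(fits)
print(f"lateral FWHM = {s.lateral_fwhm_um:.4f} um, axial = {s.axial_fwhm_um:.4f} um")
```

prints

```
t = 0.6010, t_norm = 0.6010, R = 0.8500
lateral FWHM = 0.2815 um, axial = 0.8155 um
```

The measured transparency recovers the true contrast attenuation 0.6 to
within the read noise, the retained size recovers the true scale factor
exactly (landmarks are noise-free here), and the recovered FWHMs match the
true values $2.3548\sigma$ (0.2826 um lateral, 0.8242 um axial) to about
1% despite the noise — the 200 nm top-hat term in the fit removes the bias
the finite bead size would otherwise add.

## Command line

For real data, each specimen is described by an annotation JSON (image
paths, pixel size, the four ROIs, landmark coordinates; see
`clearquant.image_io.AnnotationDocument`):

```bash
clearquant transparency --config config.json --out results/
clearquant psf          --config config.json --out results/
clearquant all          --config config.json --seed 1 --out results/   # with simulate section
```

Outputs are plain CSV (`results.csv`, `group_summary.csv`,
`pairwise_tests.csv`, `bead_fits.csv`, `fwhm_summary.csv`) plus a manifest
recording `h_max`, the package version and a config hash; reruns with the
same inputs and seed are byte-identical.

## Layout

```
src/clearquant/
  image_io.py       TIFF + annotation JSON + results CSV I/O
  transparency.py   ROI means, Michelson contrast, t and t_norm
  morphometry.py    landmark distances, retained size, medulla height
  psf_fitting.py    bead detection, profile extraction, Gaussian⊗top-hat fit
  group_stats.py    boxplot summaries, Mann–Whitney–Wilcoxon tests
  synthetic_data.py grating scenes, bead stacks, annotated cohorts
  pipeline.py       end-to-end analyses, manifests
  cli.py            `clearquant` command group
docs/methods.md     model, assumptions, parameter choices, limitations
```
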