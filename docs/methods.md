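# Methods

This note documents the models, parameters and design choices behind
`rpcseg`, in the order data flows through the pipeline.

## Annotation taxonomy and class merging

Structures are annotated as one of twelve original classes (normal ducts,
cancer, in situ neoplasia, islets of Langerhans, acinar tissue,
atrophic/metaplastic parenchyma, adipose tissue, vessels, nerves, uncertain,
lumina, lymphoid/inflammatory infiltrates) and merged for segmentation into
background (0), normal ducts (1), cancer + in situ neoplasia (2), other
epithelium (3) and fat (4), with 255 reserved for "uncertain".  Vessels,
nerves and lymphoid infiltrates count as background, as does stroma.
Internal original codes are 10–21 so the original and target code spaces
never collide and merging is idempotent.

Open design points resolved here:

* **Lumina.**  A lumen is the interior of a duct-like structure, so a lumen
  polygon inherits the target class of the smallest annotated structure
  enclosing it (probe point: the lumen's representative point); a
  free-standing lumen is background.
* **Uncertain.**  Displayed (white in overlays) but excluded from the loss
  and from every metric numerator and denominator via the ignore code.
* **Pixel convention.**  0-based indices; a pixel (row r, col c) belongs to a
  polygon iff its center (c+0.5, r+0.5) lies in the polygon interior.  An
  axis-aligned 10×10 rectangle at the origin therefore covers exactly 100
  pixels.  Later polygons in file order overwrite earlier ones, except that
  background-class structures (vessels/nerves/lymphoid) never erase cancer —
  cancer annotated inside a vessel stays cancer.

## Synthetic cohort generator

The generator exists so that patch sampling, normalization, training,
stitching and cross-validation can be exercised end-to-end with known ground
truth.  Geometry and color are strictly separated:

* **Geometry** (per-case seed): cancerous ducts are thick-walled
  (≈6 px), jagged rings (radial Fourier perturbation, relative amplitude
  0.22) with dense nuclear stippling; normal ducts are smooth thin-walled
  (≈3 px) rings around a clear lumen; other epithelium is clustered blobs;
  fat is pale disks; stroma is textured pink background.  Shapes are placed
  without overlap at uniformly random free positions (found exactly via FFT
  cross-correlation of the occupancy mask with the footprint) until each
  class reaches its target area fraction — defaults 16% cancer, 10% normal
  ducts, 8% other epithelium, 6% fat.  On canvases below 256 px the structure
  radii scale proportionally so the same mixture stays packable.
* **Color**: per-pixel hematoxylin/eosin "concentrations" are rendered to RGB
  by Beer–Lambert transmission `I = 255·10^(−(c_H v_H + c_E v_E))`, then
  passed through the scanner profile: per-channel gamma, small
  brightness/contrast offsets, Gaussian sensor noise (σ ≈ 2–2.5 8-bit units).
  Masks depend only on the geometry seed, so the same tissue can be rendered
  under every scanner — the controlled setting used by the normalization
  tests.

Four built-in profiles mimic a realistic clustering: `philips` (reference
basis) and `hamamatsu` close together, `leica` moderately shifted, and
`3dhistech` strongly divergent (stain basis mixed by 0.22/0.16 toward the
opposite stain, gamma 1.25/0.88/1.12).  Scanner divergence is deliberately
expressed through the stain basis and gamma — both exactly representable in
optical-density space — with only mild additive offsets, so that
deconvolution-based normalization is applicable in principle and its benefit
is attributable.  Cancer remains distinguishable from normal ducts after
normalization by geometry and texture (wall thickness, jaggedness, nuclear
stippling), not color alone.

What the generator does **not** emulate: real nuclear morphology, staining
batch effects that vary within a slide, tissue folds/artifacts, compression
noise, and annotation error.  Passing the desk-scale tests therefore shows
the pipeline's machinery is correct and that normalization closes the
synthetic scanner gap; it does not certify performance on real slides.

## Patch sampling

Training windows are 512×512 px at stride 256 (50% overlap), fully inside the
ROI (no padding; boundary strips narrower than one stride are not sampled at
training time).  A window is kept iff at least one *foreground* class covers
≥ 10% of the window area — inclusive threshold, full window area as
denominator; background and ignore never qualify a patch.  Per case and
class, at most 50 patches are kept, subsampled uniformly with a fixed seed;
a patch kept for any of its classes is kept once.

## Stain normalization and augmentation

Normalization is singular-vector ("Macenko-style") stain deconvolution:
optical densities `OD = −log10((I+1)/256)` of tissue pixels (total OD > 0.15)
are projected onto their leading 2-D plane; the 1st/99th percentile angular
extremes give the hematoxylin and eosin vectors (hematoxylin = larger
red-channel OD); per-pixel concentrations are non-negative least squares
against this basis; each stain's 99th-percentile concentration is rescaled to
the reference's, and RGB is re-rendered in the reference basis.  The built-in
reference is fitted once to a canonical noise-free synthetic tile, so images
already matching the reference distribution pass through nearly unchanged
(mean per-channel error < 2 units).  Blank patches (too few tissue pixels)
are returned unchanged with a warning.  A Reinhard-style CIELAB
mean/variance-matching method is available via `method="reinhard"`.
Normalization is applied per patch, identically at training and inference
time.

Augmentation draws one geometric transform (right-angle rotation × optional
horizontal/vertical flips, identity included) applied to image and mask
alike, plus color jitter on the image only: brightness/contrast/saturation
±10%, hue ±0.02 — mild, conventional ranges, all configurable and symmetric
about the identity.  Jitter steps with zero range are skipped exactly.

## Segmentation model and training

The network is a compact two-level U-Net implemented directly in numpy
(channels-last; 3×3 same-padding convolutions computed as nine shifted
GEMMs): `3→C→C | pool | →2C | pool | →2C | up+skip →2C | up+skip →C → 5`,
ReLU activations, no normalization layers, ≈42k parameters at the default
width C=16.  Widths are configurable (`small_unet_<C>`); tests and the
desk-scale runs use C=8 or smaller.  Analytic gradients are verified against
central finite differences in the test suite.

Five output channels (background explicit) pass through independent sigmoids
and are trained with per-channel binary cross-entropy on one-hot targets;
ignore pixels carry zero loss weight.  Multi-class resolution at inference is
the argmax of the sigmoid scores (ties → lowest class code).  Optimization is
Adam (default learning rate 1e-4; the desk-scale configuration uses 3e-3 for
fast convergence of the narrow model), at most 30 epochs with early stopping
after 7 epochs without validation-loss improvement; the best epoch's weights
are returned.  The validation split is drawn at case level (20% of cases, at
least one), never at patch level, so overlapping patches cannot leak across
the split.  All randomness (splits, shuffling, augmentation, initialization)
flows through generators seeded from the run seed; two runs with the same
seed and data produce identical histories.

## Stitched inference

Test-time prediction slides a 512 px window at stride 256; the final row and
column of anchors are clamped to the ROI border so coverage is complete, and
ROIs smaller than one window are reflect-padded for inference only.  Pixel
scores are blended as a weighted average with a separable raised-cosine
(Hann²) window floored at ε = 0.01 — strictly positive, symmetric, peaked at
the patch center.  The average conserves constants exactly (if all covering
patches agree at a pixel, the output equals that value to machine precision),
is invariant to patch visit order, and degenerates to plain tiling when
stride = patch size.  RPC burden is reported as the cancer-class pixel count
of the stitched argmax mask.

## Evaluation

Per case, prediction and truth masks (all ROIs pooled at pixel level) are
scored one-vs-rest per class: `F1 = 2TP/(2TP+FP+FN)`, the pixel-level Dice.
Truth-ignore pixels are excluded from every count.  The headline per-case
score is the **cancer-class F1** (the quantity of clinical interest); a macro
mean over defined classes is also reported.  A class absent from both masks
is undefined and excluded from means — scoring it 0 or 1 would punish or
reward cases for missing tissue.  Per-scanner summaries are the mean headline
F1 with a t-based 95% CI (`t(n−1)`, needing n ≥ 2; flagged otherwise).

## Cross-validation and meta-analysis

Leave-one-scanner-out internal–external cross-validation: each scanner in
turn is the external test cohort; the model trains on all other scanners'
cases; a final model is additionally trained on all data.  Fold summaries
(mean, SE over cases) enter a random-effects meta-analysis:

* **τ² by REML**, Fisher scoring on the restricted likelihood (projection
  form; tolerance 1e-10, ≤ 100 iterations, floored at 0, bracketed
  root-finding fallback).
* **Pooled mean** by inverse-variance weights `1/(se² + τ²)`.
* **CI** by the Hartung–Knapp–Sidik–Jonkman variance
  `Σw_i(y_i−µ̂)²/((k−1)Σw_i)` with a `t(k−1)` quantile, and a Jackson-style
  hybrid safeguard: the interval is never narrower than the z-based Wald
  random-effects interval (inert on well-behaved inputs, where HKSJ is the
  wider of the two).
* **Heterogeneity**: Cochran's Q on fixed-effect weights; `I² =
  100τ²/(τ²+s²)` with the typical within-study variance s²; Q-profile
  intervals for τ² (χ²(k−1) bounds on the generalized Q) and, transformed,
  for I².  Q-profile intervals are approximate for small k.

When pooling printed summaries, SEs are reconstructed from 95% CIs as
`(upper−lower)/(2·1.96)`, assuming symmetric normal intervals — the only
information a printed table carries.  The implementation was cross-checked
against R `metafor` (REML, Knapp–Hartung) on four-study inputs; agreement is
≈ 1e-5 on the pooled mean and τ².

## Desk-scale problem sizes

The full training path is exercised at sizes chosen for a single CPU: a
4-scanner × 6-case cohort of 256×256 px ROIs, 128 px patches at stride 64, a
width-8 network, batch size 8, learning rate 3e-3, 8 epochs.  At these sizes
one fold trains in roughly a minute and the complete leave-one-scanner-out
run (4 folds plus a no-normalization contrast fold) finishes in under ten
minutes, reaching cancer F1 well above 0.9 on every held-out synthetic
scanner.  These sizes are the package's test-scale defaults; the documented
full-scale parameters (512 px patches, width-16 model, 30 epochs) are the
intended configuration for real cohorts.

## Known limitations

* The numpy network is CPU-bound and narrow; it is a faithful, fully tested
  encoder–decoder, not a performance-competitive backbone for gigapixel
  workloads.
* Macenko-style normalization assumes two stains and Beer–Lambert color
  formation; strong intensity-space tone curves (aggressive
  brightness/contrast remapping) violate the model and degrade the
  correction.
* Per-patch basis estimation can be unstable on nearly mono-stain patches;
  such patches fall back to the unnormalized input with a warning.
* The synthetic cohort's class geometry is far easier than treated pancreatic
  ductal adenocarcinoma morphology; absolute F1 values on it are not
  comparable to real-slide performance.
* Q-profile CIs for τ²/I² and the SE reconstruction from printed CIs are
  approximations; with k = 4 studies all heterogeneity statistics carry wide
  uncertainty.
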