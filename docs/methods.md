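# Methods

## The problem setting

A voiding cystourethrogram is a sequence of fluoroscopic images acquired
while the bladder fills with contrast and empties.  Four diagnoses are read
from it: bladder abnormality (binary), urethral abnormality (binary), and a
left and right vesicoureteral-reflux (VUR) grade on the 0–5 International
Reflux Society scale (1 = contrast reaches the distal ureter only; 2 =
reaches a non-dilated pelvis; higher grades add dilation, tortuosity, and
by 4–5 blunted calyces).  Two facts shape the architecture: a lesion is
visible on only a subset of the exam's images, and the urethra can only be
assessed during voiding.  The patient-level label is therefore not a simple
function of any single image, which is why a learned per-task weighting
over images is used instead of manual image selection.

## Phantom generator

Clinical VCUG data are private, so the package ships a procedural phantom
whose contract is (i) exact label–appearance consistency and (ii) monotone
grade morphology; it makes no claim to photorealism.

* **Anatomy.**  Bladder: filled bright ellipse with jittered center/axes; a
  protruding round lobe for the `diverticulum` subtype, a sinusoidal
  boundary perturbation for `trabeculation`.  Urethra (voiding phase only):
  a descending tube; `posterior_valve_dilation` widens the proximal
  segment, `stenosis` pinches a focal waist with upstream dilation.
  Reflux per side: a curve ascending from the bladder toward the renal
  region whose extent (partial at grade 1, full with a pelvis blob at ≥2),
  width, tortuosity amplitude, and calyceal lobes (≥4) are all
  nondecreasing in grade.  Gaussian blur (σ = 0.7 px) then additive
  Gaussian noise (sd = 0.05) finish the render.
* **Sides** are defined in image coordinates: the left half of the array is
  the patient's left.  This is documented, deliberately not the
  radiological convention, and horizontal flips are therefore label-
  corrupting and never used as augmentation.
* **Visibility.**  Each lesion renders on a given image with probability
  `visibility` (default 0.85).  Per-image labels always reflect what was
  actually rendered — an invisible lesion yields the normal label for that
  image — so most images of a refluxing patient are labeled grade 0, and
  patient truth relates to image labels as a max-over-images under partial
  observation.  This reproduces exactly the image-vs-patient gap the
  stage-2 aggregator must bridge.
* **Defaults** (chosen once as plausible cohort structure): grade
  distribution (.70, .05, .05, .10, .06, .04) per side, independently per
  side; P(bladder abnormal) = 0.30; P(urethra abnormal) = 0.25; 2–6 images
  per exam with at least one voiding image; 64-px frames.  Synthetic
  demographics (sex ≈ 61% male, gamma-distributed age in months) are
  attached so cohort summaries have content.

What passing tests on phantoms shows: that the architecture can bind
pixel-level evidence to the right task heads, that the aggregator finds the
informative image, and that the statistics are calibrated.  What it cannot
show: robustness to fluoroscopic artifacts, anatomical variation, contrast
dynamics, or distribution shift between hospitals — none of which the
phantom models.

## Image-level model

Standard pre-norm ViT on 1-channel input; per-image min-max normalization
to [0, 1] then (x − 0.5)/0.5.  Presets: `tiny` = 64 px images, 8 px
patches, 64-dim embedding, depth 4, 4 heads, MLP ratio 2.0 (the desk-scale
default, trained from random init); `base` = ViT-Base geometry
(224/16/768/12/12, MLP ratio 4) for loading external pretrained weights —
supported but never required.  Query/key RMS normalization keeps attention
logits bounded (small-data training otherwise destabilizes).  Zero-
initialized heads make an untrained model emit exactly uniform
distributions.

Attention rollout: per layer, heads are averaged, the identity is added and
rows renormalized; the matrices are chain-multiplied across layers; the
class-token row restricted to patches is min-max scaled to [0, 1] (an
all-constant row maps to zero).  The segmentation decoder is a linear
4-class head per patch token, bilinearly upsampled, with foreground logits
biased by λ_att · saliency (λ_att = 1 by default; the bias is treated as a
constant in the backward pass).  The per-pixel max probability is the
confidence map.

## Patient-level model

Features are the frozen encoder's class tokens (the same feature the
classification heads consume).  Four task-specific query vectors with
per-task key/value projections (initialized near identity) implement scaled
dot-product attention over images; linear heads classify the pooled
vectors.  Exams keep their native length — no padding; a checksum asserts
the backbone is bit-identical before and after stage-2 training.  Dot-
product attention (rather than an additive form) and four queries (rather
than a shared VUR query) were open choices; both are the minimal mechanism
for per-task image weighting.

## Training objective and recipe

Total loss = Σ_t λ_t · CE_t + λ_seg · (confidence-weighted pixel CE + soft
Dice over the 4 classes).  Defaults and the reasoning behind them:

* λ = (4, 2, 2, 2) for (bladder, urethra, L-VUR, R-VUR) and λ_seg = 1.2.
  With equal weights the bladder task is crowded out: single-task probes
  reach AUC ≈ 1.0 where the equal-weight multitask run plateaus near 0.75,
  so the imbalance is interference, not signal shortage.
* Classification CE uses inverse-frequency class weights (grade 0
  dominates) and label smoothing 0.1.  Pixel CE uses *square-root*
  inverse-frequency weights — full inverse-frequency over-rewards recall on
  the thin classes and widens their masks.
* Soft Dice is computed per image over the classes present in that image's
  reference mask, then averaged: batch-pooled Dice dilutes the gradient of
  structures that occupy ~1% of pixels on a minority of images.
* The segmentation term is off for the first 4 epochs
  (`seg_warmup_epochs`), letting the classification tasks shape the trunk
  first.
* Optimizer: AdamW, lr 3e-3 with 1-epoch warmup and cosine decay, weight
  decay 1e-4, β = (0.9, 0.95) — the low β₂ adapts within the short
  (≈570-step) budget — global-norm gradient clipping at 1.0, batch 16,
  30 epochs, and an EMA of the weights (decay 0.99) adopted as the final
  model.  Optional per-image translation augmentation exists
  (`aug_translate`) but defaults to 0; flips are deliberately not offered.
* Stage 2: AdamW lr 5e-3, 120 epochs over 200 exams, uniform task weights;
  only the query bank, projections and patient heads train.
* Splitting is at the patient level, size round(0.7·N) half-up (1270
  patients → exactly 889/381); duplicate ids are rejected.

Divergence (non-finite loss or activations) aborts with the epoch/step or
layer index.  Two CPU runs with the same seed are bit-identical.

## Study sizes and runtime

The self-validation study (`cystovit.study`) trains stage 1 on ~300 images
(the first exams of a 90-patient pool), evaluates on 100 held-out patients
(~400 images; Dice on 60 exams), trains stage 2 on 200 exams and evaluates
on 100; the weighting probe builds 20 four-image exams in which exactly one
image shows a grade-4 left reflux and checks that it receives the maximal
left-VUR weight.  Bootstrap calibration simulates a binormal scorer with
true AUROC 0.8 at n = 200 and measures 95%-interval coverage over 500
replications (B = 2000, vectorized).  The whole study runs in ~2–3 minutes
on one CPU; sizes were chosen to keep it there.

## Statistics

AUROC is the Mann–Whitney probability with midrank ties; 6-class tasks use
one-vs-rest AUROC per grade present, macro-averaged, with absent grades
excluded under a logged warning.  CIs are seeded percentile bootstraps
resampling subjects (B = 2000); degenerate resamples are redrawn and
counted.  Kappa is unweighted Cohen's kappa (linear/quadratic variants
behind a flag); two constant identical raters give κ = 1 with a warning.
Reader comparisons use the paired two-sided t test; a constant nonzero
difference (zero variance) is flagged as degenerate rather than reported as
an infinite statistic.  Percentages round half-up to two decimals.

## Numerical and serialization choices

float32 throughout the networks; float64 in statistics.  All randomness
derives from one integer seed fanned out into named SHA-256 substreams
(phantoms, split, init, shuffle, bootstrap), so a single integer reproduces
a run.  Masks are indexed PNGs with the fixed palette 0 = black background,
1 = red bladder, 2 = yellow ureter, 3 = green urethra; manifests are CSV
with a JSON mirror; checkpoints are single `.npz` files carrying config and
a version stamp.  Pixel coordinates are 0-based, row-major, origin top-left.

## Known limitations

* The segmentation decoder works at patch resolution: with 8-px patches a
  ~3-px-wide midline urethra that straddles the central patch-column
  boundary cannot be localized more tightly than the interpolation cone
  allows.  Perfect patch-level prediction caps its Dice near 0.65; measured
  values sit around 0.45–0.58 depending on the run, while bladder (~0.93)
  and background (~0.98) are comfortable.  A higher-resolution decoder
  would remove this ceiling but is outside the present design.
* Desk-scale training from random init is run-to-run variable: held-out
  macro AUROCs move by several points across seeds, and an occasional draw
  leaves one task a few points under its typical value.  The EMA, QK
  normalization, clipping and warmup above are what reduced this variance;
  they do not eliminate it.
* The phantom's independence assumptions (left/right grades independent,
  images exchangeable given truth) are simplifications; real exams have
  temporal structure the aggregator deliberately ignores.
* `base`-preset weights must be supplied externally; nothing downloads.
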