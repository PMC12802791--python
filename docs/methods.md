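# Methods

## The problem

During stent-retriever thrombectomy for acute ischemic stroke, the operating
team watches the procedure under fluoroscopy.  The stent's platinum markers
("dots") are radiopaque and clearly visible; the clot is radiolucent and
invisible.  When the stent expands into the clot, the clot's resistance
indents the stent wall, and the markers riding on that wall are displaced
toward the vessel axis.  The package learns to invert this: given only a
binary mask of marker positions, predict a binary mask of the clot's
location and shape.

Bench-side, ground truth is obtainable by opacifying an in-vitro clot with
barium sulfate — possible for training data only, never in a patient.  That
asymmetry shapes the whole pipeline: training-style scenes render the clot
visibly (so its mask can be recovered by thresholding), test-style scenes
render it invisible (the clinically realistic condition), and the network
input must carry no trace of the difference.

## Synthetic scene model

Because no public dataset of marker/clot mask pairs exists, the package
ships a scene simulator (`thromboseg.simulate`) that serves as the ground
truth source for every test.  What it emulates, and what it deliberately
does not:

**Geometry.** A straight projected vessel of configurable lumen width
(default 16 px at the default 128-px frame, standing in for a 2 mm inner
diameter) runs horizontally with a gentle sinusoidal jitter of the
centerline (amplitude ≤ 2 px).  The stent occupies the distal ~70 % of the
visible axis, inset at the distal end so markers stay clear of the
annotation border band.  Five marker clusters sit at even arclength
fractions; each cluster holds three markers fanned across the lumen at
vertical offsets (−0.35 D, 0, +0.35 D) and staggered ±4 px in arclength,
mimicking the helical marker arrangement of a real retriever.  The stagger
also guarantees that marker disks never slice the clot mask into separate
components.

**Clot.** One contiguous sub-span of the stent with an elliptical
half-thickness profile; length uniform in 0.3–0.6 of the stent span,
mid-span thickness uniform in 0.4–0.9 of the lumen diameter.  Columns where
the profile drops below one pixel are trimmed so the rasterized mask is a
single 4-connected component.

**Deformation.** A marker at vertical offset `off` whose arclength position
falls inside the clot span is displaced toward the axis by
`min(gain * h(x), |off| - (marker_radius + 1))` where `h(x)` is the local
clot half-thickness and `gain` defaults to 0.6.  The cap keeps markers
apart and inside the lumen; displacement is monotone non-decreasing in clot
thickness, and the central marker (offset 0) never moves.  This is the
entire signal available to the network.

**Rendering.** Dark-on-light polarity: background 200/255, markers and
microcatheter distractor 30, opacified clot 110, burned-in annotation
glyphs 10 inside a 10-px border band.  Rendering order clot → annotations →
distractor → markers, then Gaussian blur (σ = 0.5 px) and additive Gaussian
noise (SD 2 gray levels), clipped and quantized to 8 bits.  Every random
draw is consumed whether or not its feature is enabled, so two scenes
sharing a seed and differing only in a flag (e.g. `distractor_enabled`) are
otherwise pixel-identical — that is what makes the distractor-robustness
comparison a paired one.

**Not modeled:** the lateral view of a biplane acquisition, curved or
branching vasculature, physically based X-ray attenuation, scatter,
heterogeneous contrast/brightness across machines, and clot-composition
effects.  Passing tests therefore demonstrate that the method recovers clot
geometry from marker displacement under controlled conditions; they say
nothing about detector physics or anatomical variability.

## Preprocessing

`to_grayscale` collapses RGB with BT.601 weights (0.299, 0.587, 0.114).
`remove_text_annotations` overwrites a fixed border band with the image's
modal intensity — annotations live only there, so no interior pixel is
touched.  `extract_dot_mask` keeps pixels at or below the marker threshold
(default 70); `extract_clot_mask` keeps the mid-gray band (default 80–160)
and retains the largest 4-connected component, with ties broken by scan
order.  Defaults bracket the simulator's intensity model with wide noise
margins and are plain config fields.

Two canonicalization steps sit between raw thresholding and the training
pairs; both were motivated by a measured failure mode and both are
defaults that can be switched off:

* `normalize_dot_mask` replaces every thresholded marker blob with a disk
  of its area-equivalent radius (`round(sqrt(area/pi))`) at its centroid.
  Blur mixes marker intensity with the surroundings, so raw thresholded
  disks come out slightly fatter on top of an opacified clot than on plain
  background — an intensity leak that exists only in training-style images,
  and one a network readily exploits at the expense of radiolucent-clot
  generalization.  After normalization, paired training-style and
  test-style renders of the same geometry yield pixel-identical inputs
  (a property the test suite asserts directly), while marker centroids
  (the displacement signal) and the marker/distractor size distinction are
  preserved.
* `fill_marker_holes` fills interior holes of the thresholded clot target.
  Markers occlude the opacified clot, so the raw target has disk-shaped
  holes that the evaluation ground truth does not have.

The microcatheter distractor is deliberately *not* removed from the dot
mask: robustness to it is a property the trained model must exhibit, so it
must be present in training inputs.

Mask resizing is nearest-neighbour with a floor convention
(`src_index = floor(dst_index * src_size / dst_size)`), which keeps masks
strictly binary; at the default configuration scenes are generated at the
model resolution and no resize occurs.

## Network

`thromboseg.model` implements a compact U-Net-style encoder–decoder as a
self-contained NumPy module (`thromboseg._nn` provides im2col convolutions
over BLAS matrix products, pooling, upsampling, and Adam; backward passes
are hand-written and verified against finite differences in float64).
Predictions are a pure function of (weights, input); training is
bit-reproducible for fixed seeds on a fixed BLAS build.

Default architecture (all overridable through `UNetConfig`, so the
hyperparameter search described for the original model can be re-run):

* average-pooling stem, factor 2 — the convolutional core operates on a
  64² grid while fractional-occupancy values preserve sub-pixel marker
  displacement information;
* depth 3; filters 4, 8, 16 in the encoder, 32 in the bottleneck
  (`base_filters = 4`, doubling per stage, cap 64); 3×3 kernels, 2×2 max
  pooling, ReLU;
* decoder stages: nearest-neighbour upsample → skip concatenation → 1×1
  fusion convolution → 3×3 convolution (a transposed-convolution upsampling
  mode is also provided);
* 1×1 sigmoid head, followed by factor-2 *linear* upsampling of the logits
  back to the input grid, so the 0.5-probability contour interpolates
  between coarse cells instead of following blocky nearest-neighbour edges.

The receptive field at the bottleneck spans several marker-cluster
spacings, which is what interpolating the clot boundary between clusters
requires.  The defaults were chosen, together with the learning rate, by a
small search over the synthetic validation split; they are sized so a full
desk-scale training run completes in minutes on a single CPU core.

He-normal initialization, seeded.  Weights serialize to a single `.npz`
container embedding the architecture config and a fingerprint of the
training configuration.

## Training

The loss alternates per epoch between pixel-wise binary cross-entropy
(even epochs) and a differentiable soft-IOU loss (odd epochs),

    L_iou = 1 − (Σ p·t + ε) / (Σ p + Σ t − Σ p·t + ε),   ε = 1 px,

computed per image and averaged over the batch.  BCE alone is dominated by
the overwhelming background class; soft IOU directly optimizes the reported
overlap quantity and equals `1 − IOU` exactly for binary predictions as
ε → 0 (a cross-module consistency test enforces this against the evaluation
module).  ε makes the empty-vs-empty case exact and keeps gradients finite.
The alternation granularity (per epoch) and a block variant (`"A:B"`), plus
a two-class soft-IOU option, are config choices; the foreground-only soft
IOU is the default.

Optimizer Adam at 1e-3 (constant), batch size 32, 150 epochs at desk scale
(the full-scale configuration of 1,000 epochs is a config change), 15 % of
the training pairs held out as a seeded validation split.  After every
epoch the mean 2-class IOU of the binarized validation predictions is
recorded, and the returned weights are the best-validation checkpoint.  A
non-finite loss aborts with `TrainingDivergedError`.  BCE predictions are
clamped to [δ, 1−δ] (δ = 1e-7) in the reported value; the gradient uses the
exact unclamped expression (p − t)/N.

## Evaluation

Per test image: 2-class mean IOU (unweighted mean of background IOU and
clot IOU — the standard semantic-segmentation definition; the clot-only IOU
is reported alongside since a single headline number cannot disambiguate
the two), pixel AUROC computed on the pre-binarization probability map
(rank/Mann–Whitney formulation with midrank ties, via scikit-learn; a
binary predictor would collapse the ROC to one point), and pixel accuracy.
Binarization threshold 0.5 with ties to foreground.  Empty-union IOU is
1.0 by convention; a single-class target makes AUROC undefined and raises.

## Summary statistics

For each metric over the test set: Shapiro–Wilk at α = 0.05, then mean,
sample SD (n−1), SEM, and the 95 % t-interval μ ± t₀.₉₇₅,ₙ₋₁·s/√n, on the
percent scale, with half-up rounding to two decimals in formatted output.
When normality fails, the interval is still printed but flagged as
descriptive.  `infer_sample_size` scans integer n for which the t-interval
half-width (given s) rounds to a printed value; for s = 2.20 and half-width
2.73 the unique n in [2, 100] is 5, which is the sample size the package's
worked examples adopt (stated as inferred wherever used).  Recomputing the
corresponding AUROC interval from the rounded mean/SD reproduces the printed
lower bound exactly and the upper bound to within 0.02 — the difference is
consistent with the original values having been computed from unrounded
inputs.

## Numerical and degenerate-case choices

* float32 network compute; float64 for losses, metrics and statistics.
* Max-pooling ties route the gradient to the first maximum (deterministic).
* `predict` clips probabilities to the open interval (1e-7, 1 − 1e-7).
* Zero-variance samples make Shapiro–Wilk undefined: summaries carry
  `normality_ok = None` and NaN for W and p rather than a fabricated value.
* A clot pixel 4-disconnected by surrounding marker disks is dropped by the
  largest-component rule of `extract_clot_mask`; this affects at most a few
  pixels per scene and is exercised by the exactness tests.
* Half-up decimal rounding is used only for formatted report output, never
  inside computations.

## Desk-scale experiment sizes

The end-to-end experiment that the acceptance script and the heaviest test
run uses 300 training + 5 test scenes at 128², 150 epochs, batch 32 — sizes
chosen so the whole experiment, including scene synthesis, runs in a few
minutes on one CPU core while leaving enough signal to recover held-out
mean 2-class IOU well above the 0.70 property threshold.  The 5-image test
set mirrors the sample size inferred from the published interval widths.

## Known limitations

* The simulator's deformation model is a capped linear response; real
  stent-clot mechanics (and hence real marker displacements) are richer.
* Only the anteroposterior projection is modeled; no 3-D reconstruction.
* Thresholds assume the controlled-contrast regime; no normalization
  across heterogeneous acquisition settings is attempted.
* The NumPy training loop is single-core by design; at the full-scale
  configuration (908² inputs, 1,000 epochs) it is not competitive with a
  GPU framework — the package targets the desk-scale regime.
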