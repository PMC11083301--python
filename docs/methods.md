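# Methods

`marrowmeter` quantifies bone-marrow cellularity — the share of the marrow
occupied by hematopoietic tissue as opposed to adipose tissue — from H&E
histology images, and provides the statistical machinery used to validate
such an automated reader against panels of human observers. Because no
clinical whole-slide images ship with the package, a first-class synthetic
histology generator provides seeded imagery with exact per-pixel ground
truth; every downstream stage is developed and tested against it.

## Segmentation model

The core is per-pixel (semantic) segmentation of RGB tissue into two
classes, hematopoietic (`HEMATO = 0`) and adipose (`ADIPOSE = 1`). A third
label value, `IGNORE = 2`, exists only on the annotation side: it marks
bone trabeculae, erythrocyte lakes, and artifacts that must not contribute
to training. The loss is categorical cross-entropy averaged over
non-IGNORE pixels only; the gradient at a masked pixel is identically
zero, so arbitrary targets there can never influence the weights. IGNORE
is never a prediction target: at inference every pixel is argmaxed over
the two tissue classes (ties go to the lowest index, i.e. HEMATO, so
prediction is deterministic).

Two fully convolutional backbones are provided, both implemented on a
compact numpy engine (`marrowmeter.nn`: im2col convolution, stride-2
transposed convolution, ReLU, Adam). The engine is single-threaded pure
numpy, which buys exact bit-level reproducibility from one integer seed.

* `SMALL_CNN` (default): a 3→16→32→48 encoder with two stride-2 stages
  (overall downsampling ×4), one bottleneck conv, and a mirrored decoder
  of two kernel-2/stride-2 transposed convolutions each followed by a 3×3
  conv to suppress upsampling block artifacts, ending in a 1×1 softmax
  head (~66k parameters). Input sizes must be divisible by 4.
* `INCEPTIONV3_MIXED7`: an inception-style trunk (stem of stride-2 convs
  plus two blocks of parallel 1×1 / 3×3 / double-3×3 branches, overall
  downsampling ×16) truncated at mixed-block depth, followed by a
  nine-stage conv/deconv decoder. Weights are randomly initialised; the
  package never downloads pretrained weights. Input sizes must be
  divisible by 16.

Training uses Adam at learning rate 1e-3 (the optimiser's conventional
default), batch size 8, no augmentation by default. Optional
scanner-style augmentation draws, per training image, random channel
offsets (`color_jitter`, intensity units), per-channel gain
(`gain_jitter`, fractional), and a Gaussian blur (`blur_jitter`, max
sigma in px). These three knobs deliberately span the same perturbation
family as the synthetic second-scanner model (below); enabling them is
what makes slide scores stable across simulated rescans. The numeric
loss is computed from softmax probabilities clipped at 1e-12; an
all-IGNORE batch contributes nothing; a NaN loss aborts training with a
diagnostic rather than continuing silently.

## Synthetic histology

The generator caricatures the two compartments by their dominant visual
difference — chromatic density:

* hematopoietic tissue: pink stroma (RGB ≈ 231,178,191) with added
  Gaussian and low-frequency "eosin blotch" noise, scattered with dark
  blue-purple elliptical nuclei (default 30 nuclei per 1000 px² of
  hematopoietic area, semi-axes ~1–3 px, coarse occupancy-grid rejection
  so nuclei spread instead of piling up);
* adipose tissue: near-white discs (fill ≈ 228,220,232) with thin pink
  rims, radii uniform in 4–12 px, placed with area feedback: discs are
  added (shrinking the final disc when it would overshoot) until the
  adipose share of non-IGNORE pixels matches the target cellularity to a
  fraction of a percent;
* IGNORE content: inside training tiles, pale-yellow elongated bands
  emulating trabecular bone (up to the spec'd `ignore_fraction` ≤ 0.3);
  around a slide's tissue core, a white glass margin (~250 intensity).

A slide's `true_cellularity` is always recomputed from the emitted mask,
never echoed from the target, so recovery experiments measure against
exact truth. Targets are met within ±5 pp across the 10–95% range.

The simulated second scanner (`rescan_variant`, ALT profile) applies
per-channel gain in [0.97, 1.03], offsets in [−8, 8] intensity units, and
Gaussian blur with sigma in [0.3, 0.7] — geometry unchanged, so the
ground-truth mask still applies. The magnitudes are a design choice
(realistic scanner pairs differ by a few percent in colour transfer and
slightly in focus), not measured from any instrument pair.

Simulated raters report `clamp(round_half_up(true + bias + N(0, sd)),
0, 100)` with a 5% rounding increment by default, matching how
pathologists conventionally report cellularity in 5% steps. Round-half-up
is the chosen tie convention. The default study panels are five "experts"
(noise sd 4 pp, biases within ±2 pp) and three "residents" (noise sd
12 pp, biases within ±8 pp) — values chosen once to produce optimal-grade
expert concordance and substantial-grade resident concordance, the
qualitative structure reported for real panels.

What the generator does **not** model: staining physics, megakaryocytes,
fibrosis, necrosis, section-thickness variation, pyramidal WSI formats.
Passing tests therefore demonstrate the pipeline's correctness and its
robustness to colour/blur perturbations, not clinical-grade performance
on real biopsies.

## Slide pipeline

Slides are consumed at native resolution (magnification is metadata).
Tiles are non-overlapping, ceil(W/ts)·ceil(H/ts) per slide; edge tiles are
padded with white and the padded pixels excluded from all areas via a
validity flag. After stitching, pixels whose three channels all exceed the
background threshold (default 235) are marked EXCLUDED — slide glass is
neither tissue. Cellularity is `100·A_h/(A_h+A_a)`; it is undefined (an
error, not 0) when both areas are empty. Stitched areas equal the sums of
per-tile areas by construction, and translation tests confirm tiling
introduces < 2 pp of boundary sensitivity. Overlays blend green
(hematopoietic) and blue (adipose) over the original image at
configurable alpha.

The inference-time background rule is this package's stand-in for
excluding non-tissue at test time; annotated IGNORE regions only exist at
training time.

## Agreement statistics

Lin's concordance correlation coefficient is computed in the standard
form

    CCC = 2·cov(x,y) / (σx² + σy² + (μx − μy)²)

with population (1/n) variances, per Lin's original estimator. It is
validated in tests against an independent expectation-form oracle,
`1 − E[(X−Y)²]/(σx²+σy²+(μx−μy)²)`, to 1e-10. The 95% CI uses the
asymptotic variance of the Fisher-z-transformed coefficient (Lin 1989;
the same expression used by epiR/DescTools), transformed back with tanh
so the interval always contains the point estimate; when ρ is degenerate
the CI falls back to the simple 1/(n−3) Fisher variance. Grades follow
Altman: CCC > 0.8 OPTIMAL, 0.6 ≤ CCC ≤ 0.8 SUBSTANTIAL (0.8 itself is not
"greater than 0.8"), otherwise BELOW_SUBSTANTIAL.

Bland–Altman analysis uses d = x − y, bias d̄, sample standard deviation
S_d (1/(n−1)), and limits d̄ ± 1.96·S_d, which cover ~95% of normal
differences (checked empirically at n = 10,000).

`pairwise_ccc_table` computes all rater-pair CCCs plus, for each rater,
the CCC against the leave-one-out panel mean — mirroring how an automated
reader is compared against the mean of a human panel without letting a
rater agree with itself.

Degenerate inputs: CCC requires n ≥ 3 and at least one non-constant
series (both constant → error; exactly one constant → CCC 0, ρ reported
as nan). Bland–Altman requires n ≥ 2.

## Study sizes used by tests and the acceptance script

All experiments are desk-scale by design: 200 training tiles of 64 px
(targets uniform in 5–95%, ignore fractions up to 0.15), a 90/10
train/validation split, 10 training epochs for the default model and 15
for the jitter-trained robustness model, and 20 validation slides of
256 px spanning 10–95% cellularity. Under these conditions the default
model reaches ≥ 0.95 masked validation accuracy, recovers slide
cellularity with mean absolute error well under 3 pp and model-vs-truth
CCC ≈ 0.997, and the jitter-trained model keeps paired
reference/rescanned scores within 2.5 pp on every slide.

## Known limitations

* The synthetic textures are linearly separable in colour to a large
  degree; a real-slide model would need far more training data and
  stain-robust augmentation or normalisation.
* The inception-style backbone reproduces the published architecture's
  shape contract and depth, not its pretrained features.
* Confidence intervals assume the asymptotic normality of the z-transformed
  coefficient; at n = 20–40 they are approximate.
* Pyramidal/proprietary WSI containers are out of scope; inputs are flat
  RGB images (PNG/TIFF).
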