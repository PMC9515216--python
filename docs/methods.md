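# Methods

## The model

The core object is population-scale *ageing attention*: given a cohort of
lateral-cephalometric-style grayscale images with decimal ages, a CNN age
regressor is trained with L1 loss, Grad-CAM is applied to its last
convolutional feature maps, and the resulting non-negative per-subject
salience maps are averaged per completed year of age into ARDA maps
`A_a = (1/N_a) Σ M_{a,n}`, `a ∈ {4, …, 40}`. Thresholding each `A_a` at the
median / 75th / 90th percentile of its own pixel values defines the
ageing-significant region; the quantified ARDA of an anatomical instance at
age `a` is the mean of `A_a` over instance-mask ∩ significant-region. The
underlying assumption is the usual attribution one: regions the regressor
relies on to move its prediction upward are regions whose appearance carries
age information.

For adult estimation, a two-channel model is trained with each subject's own
salience map (from the frozen baseline) concatenated to the image when the
subject's age exceeds the cutoff `KA`; younger subjects receive a zero
channel so a single network serves both regimes. At inference, a first-pass
baseline prediction strictly above `KA` triggers one re-estimation by the
constrained model; the second estimate is final. `KA` defaults to 25 years —
the boundary between the young (4–25) and adult (26–40) reporting
super-groups — and is fully configurable.

## The CNN engine

No deep-learning framework is used: convolution (im2col), ReLU, global
average pooling, a linear head, analytic backpropagation and Adam are
implemented directly in NumPy. This keeps the whole pipeline bit-reproducible
from a single integer seed on any CPU and makes the Grad-CAM gradients exact
rather than framework-dependent. The desk-scale backbone (`tiny-cnn`) is
three 3×3 conv/ReLU stages (8, 16, 16 channels; strides 2, 2, 1), so a 64×64
input yields sixteen 16×16 attention feature maps, followed by global average
pooling and one output unit (3 585 parameters). The EfficientNet-B0 stage
plan (MBConv blocks with squeeze-and-excitation, 224×224 input, 1280-channel
7×7 final maps) is registered structurally, and the registry counts trainable
parameters of the standard comparison family (ResNet-18/34/50/101/152,
EfficientNet-B0) by exact layer enumeration; these counts match the published
values (e.g. ResNet-50 → 25 557 032 ≈ 26 M with its 1000-way head).

### Training defaults and the intercept

Adam with lr 0.01 under cosine decay, batch 64, 30 epochs, 15 % of the
training set held out for best-epoch selection. The L1 gradient has constant
magnitude, so with Adam the step size bounds how far any parameter can move;
an output starting at 0 therefore converges unreasonably slowly toward a
cohort mean of ~22 years unless either the intercept is pre-set or the
learning rate raised — hence lr 0.01 rather than the more customary 1e-3.

The head trains **without an intercept** by default (`fit_intercept=False`).
This is an identifiability choice, not an accuracy one: with a free
intercept, the optimiser may book the age-constant component of its
prediction either on the intercept or on age-invariant image structure, and
only the latter contaminates the salience maps. The phantom makes the effect
visible — with a free intercept, a fraction of training seeds assign the
static distractor more attention than the genuinely changing structures at
the youngest ages. Removing the intercept forces the constant component
through image evidence that must vanish as predictions approach the low end
of the age range, which systematically suppresses attention on age-invariant
structure. Accuracy cost on the phantom is ≈0.3 years of MAE.

### The salience ensemble

A single small regressor still retains some seed-dependent freedom in how it
distributes constant prediction mass across image regions. The package's
standard extraction protocol (`SalienceEnsemble`, default 3 members) averages
each subject's min–max-normalised salience map over a few independently
initialised extractors before the per-age aggregation — the same variance-
reduction idea the ARDA map itself applies across subjects, applied across
training randomness. Predictions are ensemble means. Three members were
sufficient to make the phantom's changing-versus-static attention ordering
stable across training seeds; more members sharpen it further at linear cost.

## Grad-CAM details

The target layer is the post-ReLU feature map of the last convolution — the
only spatial map feeding the head, and the standard Grad-CAM attachment
point. For a regression output the backpropagated scalar is the predicted
age itself; no class selection is involved. With a mean-pool + linear head
the analytic per-channel gradient is `v_k/Z`, but the implementation
backpropagates through the head generically, and a central finite-difference
oracle verifies the weights to 1e-4 in the test suite. Upsampling to the
image grid is corner-aligned bilinear interpolation. Each subject's map is
min–max normalised to [0, 1] before aggregation (a zero map stays zero), so
subjects contribute comparably to the per-age mean; the un-normalised route
is available via `normalize=False`.

## Quantification choices

- Ages bin by completed years, `a = floor(age)`.
- Percentile thresholds are computed over all pixels of the per-age ARDA map
  (not per-subject maps), with an inclusive `≥` tie rule so a constant map is
  entirely significant.
- An empty instance ∩ region intersection yields a *missing* value, never 0:
  a zero would masquerade as measured salience. In dominance comparisons an
  instance with no ageing-significant pixels at all is treated as dominated —
  its attention is below threshold everywhere.
- The distribution band for an instance's per-subject quantified salience is
  μ ± kσ with ideal-normal coverage `100·[Φ(k) − Φ(−k)]`; k = 2 gives the
  familiar 95.45 %.

## The phantom

The synthetic cohort emulates what the analysis needs from real radiographs
and nothing more: a blank background; several labeled geometric instances
(ellipse, rectangle, ring arc, tooth row) whose linear size follows a
piecewise-linear age response — `size(a) = base·(1 + r_y·min(a, b) +
r_o·max(0, a−b))` with a developmental breakpoint `b` — static distractors;
and optional clipped additive Gaussian noise. Ages are uniform on [4, 40],
rounded to hundredths. The reference study configuration is 2 000 subjects at
64×64 with one fast instance (5 %/yr before the age-18 breakpoint, 1 %/yr
after, intensity 0.9), one slow ellipse (2 %/yr, 0.5 %/yr, 0.7) and one
static rectangle (0.8), zero noise. All study-scale shapes are solid
primitives whose features stay well above the pixel scale at every age; the
striped tooth-row renders ~2 px stripes at 64×64 young ages (below the
resolvable scale) and is therefore used only in larger-frame demos.

What the phantom does *not* emulate: anatomical texture and overlap of
projected 3-D tissue, intensity inhomogeneity, scanner artefacts, gender
effects, and correlated multi-structure growth. Passing tests therefore show
that the pipeline recovers *known, isolated* geometric age signals — they do
not certify behaviour on clinical images, where attention must separate
overlapping structures that all change to some degree.

## Preprocessing, splits, regions

Real images pass through per-image min–max scaling, CLAHE (clip limit 0.01,
~8×8 tiles; skipped for flat images, where it is undefined), zero-padding to
square, and a resize to the network input; label maps follow the same
geometry with nearest-neighbour interpolation. Augmentation is a seeded
random affine (rotation ±10°, translation ±5 %, scale 0.9–1.1) plus a
horizontal flip with probability 0.5 that toggles the recorded facing
direction. Splits are stratified over the seven age groups (4–10 … 36–40)
with largest-remainder apportionment at 0.70/0.15/0.15.

The three concentrated-region crops are fixed linear expressions of the
frame size with 100-pixel offsets defined at the ~2144×2304 reference
resolution; on frames below ~300 px the offsets scale proportionally
(`round(100·W/2144)`, `round(100·H/2304)`), since fixed 100-pixel margins
would swallow a small frame. Coordinates are (x = column, y = row) from the
top-left corner with half-open boxes; printed geometry applies to
right-facing profiles and mirrors for left-facing ones. "Discard" masks the
region to zero rather than cropping, so network input geometry is identical
across experimental conditions; selecting several regions keeps the union of
their boxes.

## Metrics

MAE ± SD of the absolute error, median signed error, IQR of the absolute
error, CS-5 (percent of subjects within 5 years) and MCS-5 per seven age
groups, the 4–25 / 26–40 super-groups, and overall. MCS-5 is implemented as
the mean of CS-j for j = 1…5 — an interpretive reading of "mean cumulative
score", isolated in one function so the definition can be swapped. Every
report is recomputed cell-by-cell by a brute-force loop inside `evaluate` as
a built-in self-check.

## Problem sizes

Default test and demonstration scales: 2 000 subjects at 64×64 with the
3 585-parameter backbone for the reference study (minutes on one CPU);
smaller cohorts for unit tests. The full-resolution EfficientNet-B0 plan is
registered and countable but not trained at desk scale.

## Known limitations

- Grad-CAM attributes only positive evidence; structure whose *absence*
  indicates youth cannot be highlighted, which is why the youngest ages are
  the hardest regime for the attention ordering.
- The salience-channel constraint uses the subject's own map from the frozen
  baseline; the population-ARDA-lookup variant (by predicted age) is
  exposed but not the default.
- One retest round only; no uncertainty quantification.
- The attention scale is relative (per-map normalisation); it does not map
  onto physical change rates.
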