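# Methods

## The model

`dermstack` classifies smartphone photographs of skin lesions into six
diagnostic categories — actinic keratosis (ACK), basal cell carcinoma
(BCC), melanoma (MEL), nevus (NEV), squamous cell carcinoma (SCC) and
seborrheic keratosis (SEK), encoded 0–5 in that order — by stacking an
image branch and a clinical-metadata branch.

**Image branch.** Each photograph is resized to 224×224×3 (box/area
interpolation when shrinking, bilinear when enlarging) and converted to
grayscale with BT.601 luma weights (0.299, 0.587, 0.114).  Two enhanced
representations are derived:

* the **black-hat transform** `closing(I, B) − I` with an elliptical 9×9
  structuring element `B`, which highlights dark structures (hairs, pigment
  network, dark borders) smaller than the kernel; closing is extensive, so
  the result is non-negative;
* **adaptive Gaussian thresholding** after a σ = 1 Gaussian blur: a pixel
  is white iff its intensity strictly exceeds the Gaussian-weighted mean of
  its 21×21 neighbourhood minus a constant C = 5 (ties black, with a 1e-9
  tolerance so exact ties are classified black regardless of float
  summation order).  The window weights use the conventional size-to-sigma
  rule `0.3·((w−1)/2 − 1) + 0.8`.  Local thresholding is robust to the
  uneven illumination of hand-held captures.

All three representations (the enhanced ones replicated to three channels)
pass independently through a patch-based transformer feature extractor —
224×224×3 → 196 non-overlapping 16×16 patches, row-major, embedded at
width 768, encoded, reshaped to a 14×14×768 spatial map.  The original
map is multiplied element-wise with each enhanced map and the three maps
are concatenated along the width axis (14×42×768).  Because the
concatenation is spatial, global average pooling of the fused map equals
the arithmetic mean of the three branch GAPs — asserted exactly in the
tests.  A single dense layer with softmax converts the pooled 768-vector
into six class probabilities.  The head is trained with a categorical
focal loss `−α·w_c·(1−p_y)^γ·log p_y` (γ = 2, α = 0.25) and
inverse-frequency class weights `w_c = N/(K·n_c)`, by full-batch gradient
descent with momentum (300 epochs, learning rate 0.05, momentum 0.9,
weight decay 1e-3, standardised inputs).  The loss is named sigmoid-focal
in some descriptions of this architecture while the output layer is a
softmax; we apply the focal modulation to the softmax probability of the
true class (categorical focal loss), which reduces to weighted
cross-entropy at γ = 0 (asserted within 1e-9).

**Clinical branch.** The metadata follows the PAD-UFES-20 schema (26
attributes).  Cleaning drops the three identifiers, the diagnostic label,
and the anatomical region (`region` is the "area" column of the schema),
encodes booleans as {0,1} and the three categorical columns
(`background_father`, `background_mother`, `gender`) as ordinal integer
codes (gradient-boosted trees are insensitive to the ordering; a frozen
category table keeps codes stable between fit and predict).  Missing
values are deliberately **not** imputed: the count of missing cells is
preserved through cleaning, and xgboost routes NaN natively at every
split.  The branch is a gradient-boosted ensemble (300 trees, depth 6,
learning rate 0.1, `multi:softprob`, histogram method, fixed seed).
`biopsied` is kept as a predictor for schema fidelity, but note it encodes
how the label was confirmed and may leak diagnostic certainty on real
data.

**Stacking.** Each sample's two 6-class probability vectors are
concatenated, image half first, into a 12-vector.  Stacked vectors for
meta-model training are strictly out-of-fold: a stratified 10-fold plan
partitions the training split, both branches are refit on the other nine
folds, and the held-out fold is predicted — so no sample's stacked vector
depends on models that saw it.  The meta-model is an L2-regularised
multinomial logistic regression (C = 1, lbfgs).  Argmax ties break toward
the lowest class code.  For deployment the base models are refit on the
full training split; the meta-model keeps its OOF-trained coefficients.

**Protocol.** An 80/20 stratified train/test split is made first; the
test size is round-half-up(0.2·n) (2298 samples → 1838/460).  A further
20% validation carve-out is taken from the training side; the default
pipeline computes it but does not consume it — the head trains for a
fixed epoch count rather than early-stopping, which keeps the entire run
bit-reproducible from one seed.  Cross-validation for stacking operates
inside the 80%.  One global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`, so repeated runs with the seeded test
backbone are identical to the byte.

## Evaluation arithmetic

All metrics are one-vs-rest per class from the 6×6 confusion matrix
(rows = truth): PPV = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean,
NPV = TN/(TN+FN).  NPV needs the total evaluated count, which is threaded
explicitly.  The overall row is the **macro** (unweighted) mean — this
aggregation rule is confirmed by exact six-decimal agreement between the
published per-class and overall tables it reproduces.  Undefined ratios
are flagged NaN with a warning, never silently zeroed, and a macro over an
undefined class is an error.

`recover_counts` inverts printed PPV/recall decimals to the minimal
integer confusion counts consistent with a known evaluation-set size:
a printed PPV of 0.840909 is the reduced fraction 37/44 and a recall of
0.948718 is 37/39 (via `Fraction.limit_denominator`), so TP must be a
common multiple of the numerators — minimally their lcm — giving
TP = 37, FP = 7, FN = 2 and TN from the total.  This lets NPV be
re-derived and checked exactly against published values.

## The backbone contract

The feature extractor is a *contract* — image in, 14×14×768 out — with two
weight sources.  The pretrained ViT-B/16 adapter (depth 12) is a hook: an
external loader must be registered, and calling it without one raises.
The **seeded test backbone** fulfils the contract for all development and
testing: a real pre-norm transformer encoder (default depth 2, 4 heads,
MLP ratio 2) whose weights are a pure function of the seed.  Design
choices made for probe-friendliness, documented here because they differ
from a trained network:

* inputs are scaled to [−1, 1] (centre 127.5, scale 127.5), identically
  for all triplet members;
* the patch-embedding matrix is initialised at unit scale while block
  weights use 0.05.  The pre-norm LayerNorms make block-output magnitude
  independent of the embedding scale, so this keeps the linear image
  statistics readable by a GAP-level probe instead of being drowned in
  random nonlinear mixing;
* there is no final LayerNorm: the residual stream retains the input's
  intensity scale, which downstream linear probes rely on;
* no class token is used; the 196 encoded tokens reshape row-major to the
  14×14 grid.

Position embeddings (σ = 0.5) make the output order-sensitive: shuffling
patches of a non-constant image changes the features, which the tests
assert.  The backbone is never trained; it is a fixed nonlinear feature
bank, and a golden checksum test pins its numerics.

## The synthetic cohort

The generator is the package's study-conditions module: every stage of the
pipeline is exercised on data with known ground truth and no downloads.
All outputs are pure functions of (config, seed).

**Images.**  A skin-toned background (base colour sampled per image, red
200–235 with green/blue offsets), a smooth linear illumination gradient
(amplitude 20), and Gaussian pixel noise (σ = 4).  The lesion is
*multifocal*: a cluster of small hard-edged pigmented lobes (radius ≈ 4 px,
centres ≥ 9 px apart) scattered over an elliptical extent.  The lobe scale
is deliberately below the 21-px thresholding window: every lesion pixel
then sits well below its background-dominated local mean, so adaptive
thresholding segments ≥ 80% of the lesion interior — a single large
uniform blob would locally look flat and threshold white in its interior,
which is a property of local-mean binarisation, not a defect of the
implementation.  Optional thin dark hair strokes (anti-aliased lines,
darkness 60–110) exercise the black-hat transform.  The planted image
signal is class-conditional: darkness contrast (base 105, step 8/class,
jitter ±6), extent (base 9 px, step 1.2, jitter ±1; lobe count grows with
extent²) and lobe-size irregularity.

**Metadata.**  All 26 schema columns.  Class-conditional clinical profiles
(age, skin-cancer and cancer history, Fitzpatrick type, diameters, the six
symptom booleans, biopsy probability) are blended about their across-class
mean by `signal_strength`; at strength 0 all classes share one
distribution (checked by a KS test).  Lifestyle/demographic columns are
punched missing independently at rate 0.35, matching the incompleteness
pattern of the real table.  The default class mix mirrors the real
cohort's imbalance (ACK and BCC dominant, MEL ≈ 2%).

**The strong-signal preset** (`SynthConfig.strong_signal`) is used for
planted-signal-recovery checks: contrast step 14 with jitter ±3 (disjoint
per-class bands), extent step 2.0, clinical effects ×1.3, and no hair —
hair is class-independent nuisance whose dark-pixel mass is comparable to
the lesion's and would confound the recovery measurement; the default
configuration keeps hair for the enhancement tests.

**What passing means.**  The cohort emulates the *structure* of the real
problem (paired modalities, class imbalance, missingness, illumination
variation, hair artifacts), not its difficulty: lesions are geometric, the
class signal is low-dimensional, and there is no inter-patient correlation,
no camera/compression variation, no label noise.  Passing the recovery
tests shows the pipeline is wired correctly and loses neither modality's
information; it does not certify clinical accuracy on real photographs.

## Problem sizes and numerical choices

The end-to-end checks run the full protocol on n = 600 synthetic samples
(480 train / 120 test) with the depth-2 test backbone — sized so a
complete run finishes in a few minutes on one CPU while the rarest class
still has ≥ 10 training members for the 10-fold plan.  Smaller fixtures
(n = 36–240) back the unit tests.

Degenerate inputs are errors, not guesses: unknown class names, duplicate
image ids, single-class training sets, classes rarer than the fold count
(with guidance to lower K), non-finite features, schema mismatches.
Probability vectors are validated to sum to 1 within 1e-6 at every module
boundary.  The focal loss clips p at 1e-12.  Head standardisation floors
the per-feature σ at 1e-8.

## Known limitations

* The pretrained-weights path is an adapter only; results in this
  repository all use the seeded test backbone.
* The image head is linear over pooled features; it is the stacking
  protocol, not the head capacity, that this package is about.
* `biopsied` as a predictor is schema-faithful but epistemically leaky on
  real data (see above).
* The scatter-ratio phrasing of "stacked vectors are more separable" is
  replaced by a probe-classifier comparison: the between/within scatter
  ratio of a concatenation is a weighted mean of the halves' ratios and
  cannot exceed the better half by construction.
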