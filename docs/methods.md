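# Methods

## The model

`flexfuse` predicts a binary disease-progression endpoint from up to four
patient modalities: a clinical table (C), a proteomic table (P), a
metabolomic table (M) and pathology image tiles (I). Each modality is
encoded to a fixed-width representation vector (`d_rep`, default 32), the
vectors are fused, and a classifier of two fully-connected layers
(hidden width 64, ReLU, sigmoid output) produces the progression
probability. Everything — feature encodings, convolutional backbone,
fusion parameters, Meta module, classifier — sits in one parameter tree
and is trained jointly by backpropagation (binary cross-entropy loss,
Adam with decoupled weight decay).

### Tabular pathway: hash mapping + encoding training

Heterogeneous tabular features (binary comorbidity indicators, Gaussian
laboratory values, long-tailed omics intensities) are first *hash
mapped*: per feature, empirical quantile boundaries (default B = 16
buckets) are fitted on the training fold, and every value is replaced by
the midpoint of its bucket's probability mass on [0, 1] — bucket k of B
maps to (k + 0.5)/B. Values beyond the fitted range clamp into the
extreme buckets; a value exactly on a boundary falls into the lower
bucket, so heavily tied features keep their mass together; a constant
feature collapses to a single bucket (midpoint 0.5). Missing cells map
to a reserved missing bucket, never to a number. This makes the input
scale-free: any monotone rescaling of a feature leaves its mapped values
unchanged.

The mapped scalar v_f then scales a trainable ten-dimensional encoding
vector e_f; a per-feature learnable affine layer (10x10, unshared by
default; a shared-weights variant is available) plus ReLU transforms it;
the per-feature vectors are summed (order-invariant) and projected with
one linear layer + ReLU to `d_rep`. Missing cells contribute a learned
per-feature missing-encoding vector m_f instead of v_f·e_f, so
missingness remains visible information rather than an imputed value.

Two ablation pathways exist for comparison: *raw* feeds standardized raw
values, and *hashed* feeds the bucket midpoints, each concatenated with
the cell-presence mask, through a plain two-layer feedforward encoder
without trainable per-feature encodings.

Whether the original "hash mapping" is exactly quantile bucketing is not
something we assert; quantile bucketing is chosen as a concrete, monotone,
scale-free realization of mapping heterogeneous features onto one scale
while partly preserving their distributions.

### Image pathway

Tiles (RGB, uniform size, read from a per-patient manifest) pass through
a small convolutional backbone; the spatial feature map of the last
convolutional stage (the "tap point") is averaged over space to a
per-tile embedding, embeddings are pooled over the patient's tiles
(unweighted mean by default; attention pooling available) and projected
to `d_rep`. The default backbone `tiny_cnn` is four valid 3x3
convolutions with channels (8, 16, 32, 32) and strides (1, 2, 2, 1):
the stride layout keeps the tap receptive field at 17 px so that SCDA
heatmaps resolve structures smaller than a quarter tile, and requires
tiles of at least 17 px (64-px tiles give a 12x12 tap map). A deeper
`small_cnn` exists for architecture-swap checks. Large pretrained
backbones (ResNet/VGG families) are not bundled; the registry accepts
user-supplied factories. Per-channel tile normalization constants are
computed on the training fold. During training, tiles are augmented with
the eight dihedral symmetries (random flips/90-degree rotations); without
this, a CNN on small cohorts memorizes patients through tile texture and
the fused model loses its multi-modal advantage — with iid synthetic
textures this failure mode is especially strong.

### Fusion and classification

Four fusion operators over the per-modality vectors h_m:
summation (Σ h_m), multiplication (elementwise product), gating
(g_m = σ(A_m[h_C; …]), fused = Σ g_m ⊙ h_m, one affine gate per
modality over the concatenation), and concatenation in the fixed order
(C, P, M, I). Summation, multiplication and gating require equal `d_rep`
across modalities. Because representations are ReLU outputs (sparse,
nonnegative), multiplication zeroes every fused coordinate at which any
modality is zero; with four modalities this destroys most coordinates,
which is the mechanism behind its degraded accuracy.

### Meta module (single missing modality)

For each target modality, a feedforward network maps the concatenation
of the other active modalities' representations to a `d_rep` replacement
vector. It is co-trained with the classifier: on complete samples a mean
squared reconstruction loss against the (detached) true representation is
added to the classification loss with weight λ = 0.5. At inference,
patients missing one modality are routed through the Meta module
transparently; more than one missing active modality is explicitly
unsupported and raises. Imputation can only help when modalities are
correlated beyond the label — see the synthetic-cohort section.

## Training and evaluation

Stratified k-fold cross-validation (default k = 5) with all fold-derived
state — quantile boundaries, standardization constants, tile statistics,
model parameters — fitted on the training fold only; every fitted
preprocessor records the patient IDs it saw, so leakage is checkable.
Optimizer: Adam, lr 3e-3, decoupled weight decay 1e-3, batch size 32,
default 40 epochs. Early stopping watches AUROC on an internal
stratified 80/20 split of the training fold; because validation AUROC on
small splits is noisy before the model starts learning, best-state
tracking begins only after a 12-epoch burn-in (patience 8). All
randomness — initialization, batch order, splits, augmentation — derives
from one seed; a rerun reproduces results bitwise. The metric panel is
AUROC, AUPRC, accuracy, sensitivity, specificity and F1 at threshold
0.5 (the identities of the original six metrics are not public; this is
the standard clinical sextet and is a package choice). A documented
deduplication utility resolves duplicate patient records before CV
(progression-group rows win, then earlier acquisition time).

## Interpretability

**Integrated Gradients** at the model-input level: for tabular
modalities the inputs are the mapped scalars and their presence
indicators, with the all-missing point (v = 0, u = 0) as baseline — the
model's native "no information" input; for images, the zero tensor in
normalized space. The path integral uses a right-endpoint Riemann sum
(default 50 steps; completeness is verified at 300 against a 10x finer
sum). A feature's attribution is the sum of its value- and
presence-components. Meta routing is a discrete mechanism and is
excluded from the attribution graph; absent modalities are represented
by the learned missing encodings instead. Completeness is reported both
per patient and batch-aggregated (mean |gap| / mean |F(x) − F(x′)|); the
per-patient ratio is ill-conditioned for patients whose prediction
barely differs from baseline. Modal importance is the mean absolute
attribution over a modality's inputs (signed variants available);
feature rankings sort by median absolute attribution with ties broken
alphabetically.

**SCDA heatmaps**: the tap-point feature map is summed over channels,
thresholded at its mean (strict inequality), and the largest 4-connected
above-threshold component becomes the region of interest; the channel
sum is upsampled bilinearly to tile resolution (the ROI mask nearest-
neighbor) for red(strong)/blue(weak) rendering and IoU scoring.
Slide-level views are mosaics of tile heatmaps.

## Synthetic cohorts

The generator emulates the structure of a multi-modal kidney cohort
without any real data. Clinical features are half Bernoulli
(p ~ U[0.1, 0.5]) and half Gaussian; proteomic/metabolomic intensities
are per-feature-scaled log-normal(0, 1) (sample skewness > 1). A chosen
subset of "informative" features enters a logistic label model with
effect size 1.0 (log-odds per SD) by default — calibrated so that a
standalone regularized logistic fit on n = 2000 with five informative
clinical features attains held-out AUC > 0.8, and chance level under a
zero effect; the intercept is solved so prevalence ≈ 0.41 (a realistic
progression fraction, 106/259). An optional shared latent patient factor
(loading `shared_factor`, default 0) induces cross-modal correlation on
continuous features — off by default to keep planted signals cleanly
separable, switched on for imputation experiments, since predicting one
modality from another is impossible under conditional independence.
Optional contamination multiplies random omics cells by a large factor
(measurement artifacts, applied after label generation so they are pure
noise). Tiles are Gaussian-smoothed noise textures; progression
patients' tiles carry a bright ellipse (semi-axis 0.14–0.26 of the tile,
random eccentricity/orientation) with probability `lesion_signal`. Every
tile — lesioned or not — records a candidate ellipse in `truth.json`, so
lesion-free tiles serve as chance-level negative controls for
localization. Modality- and cell-level missingness are applied last,
with at least one modality guaranteed per patient.

What the generator does *not* emulate: realistic histology texture,
feature-feature interaction structure beyond one latent factor,
longitudinal records, batch effects. Passing tests therefore demonstrate
that the machinery works and recovers planted structure, not clinical
performance on real cohorts.

## Reference experiment sizes

Chosen for a single-CPU desk run; all are package design choices stated
here once:

- multimodal benefit: n = 600 patients, 3-fold CV, 5 seeds, 32-px tiles,
  2 tiles/patient; clinical plants 4 informative features, proteomics 6
  (a standardized log-normal feature carries less linearly recoverable
  signal than a Gaussian one, so the counts are calibrated to give the
  two signal modalities comparable unimodal strength; metabolomics and
  images are noise).
- FET pathway ordering: n = 600, 3-fold CV, 5 seeds, outlier rate 2%
  at scale 1000 on P/M.
- fusion-operator comparison: n = 400, four modalities, 3-fold CV,
  5 seeds.
- Meta utility: n = 500, shared_factor 0.8, signal concentrated in the
  masked modality (6 of its features informative), 15 replicate seeds —
  the Meta-vs-zero AUROC gap is about one point, real but small, so it
  needs replication to measure.
- SCDA localization: n = 200 (half held out, so the IoU hit rate is
  estimated on ~60-110 lesion tiles), 64-px tiles, lesion_signal 1, zero
  tabular effect (the image alone carries the label).
- IG completeness: n = 200 four-modality cohort, 16 probe patients.

## Numerical choices and degenerate inputs

Float64 throughout; the autodiff core is a plain reverse-mode engine
over numpy with explicit gradient closures (gradient-checked against
central differences in the test suite). BCE is computed in the stable
log1p form on logits. Constant features map to midpoint 0.5; a feature
with no observed training values is a fit error naming the feature; a
single-class training split refuses to fit; AUROC on single-class labels
raises rather than returning a number. Quantile ties collapse buckets.
SCDA on a constant map yields an empty ROI (strict threshold). Zero
tiles for a patient signal a missing image modality rather than raising
mid-batch.

## Known limitations

- No pretrained image backbones; on real pathology data the small
  backbones here are not competitive — the branch is built for
  mechanism-level validation.
- The Meta module handles exactly one missing modality.
- IG on the raw/hashed ablation pathways attributes to standardized
  values/midpoints, which are less interpretable than the encoded
  pathway's native inputs.
- The generator's independence structure (one optional shared factor) is
  far simpler than real biology; effect sizes are free parameters of the
  simulation, never estimates of any real cohort.
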