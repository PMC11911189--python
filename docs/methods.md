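# Methods

`lymphrisk` models the risk that a diffuse large B-cell lymphoma (DLBCL)
patient relapses or proves refractory (R/R) to first-line chemotherapy,
from two routinely available sources: the H&E-stained whole-slide image of
the diagnostic biopsy and the baseline clinical/laboratory table. This
note records the models, the parameters that matter, the synthetic data
the package is validated on, and the numerical choices made where the
design was genuinely open.

## Slide preprocessing

A scanned slide is white glass plus stained tissue. Tissue is detected on
the HSV saturation channel at a 1/16 downsample: the channel is median
filtered (7x7), thresholded at 35 on the 8-bit scale, and the binary mask
is cleaned with a morphological opening (disc radius 4, erosion then
dilation). Thresholding saturation rather than colour makes the mask
invariant to hue, i.e. to the exact stain tint. The tissue area is then
tiled into non-overlapping 512x512 patches (stride = patch size,
coordinates 0-based, top-left anchored, half-open extents); a grid cell is
kept when at least `min_tissue_fraction` (default 0.25) of its footprint
is tissue. Patch coordinates and slide metadata persist in an HDF5 store
(`/coords`, attributes `patch_size`, `downsample`, slide geometry, mask
parameters). The reader accepts flat PNG/TIFF rasters; pyramidal formats
are read at their base level only.

## Patch encoding

Each patch maps to a 256-vector. Two encoders sit behind one interface:

* **truncated residual network** — an 18-layer residual architecture cut
  after its third residual stage (256 channels), globally average-pooled.
  "First three blocks" is ambiguous between three stages and three basic
  blocks; three stages is adopted because only that yields the stated
  256-d output. Weights load from an `.npz` file or are drawn from a
  seeded He initialiser; pretrained weights are a plug-in, never bundled,
  so the package builds and tests offline. Implemented forward-only in
  NumPy (im2col convolutions); it is an inference path, not a training
  path.
* **fixture encoder** (default for synthetic work) — closed-form patch
  statistics (per-channel mean/variance/min/max and a 16-bin saturation
  histogram) through a fixed seeded Gaussian projection to 256 dims. It is
  deterministic, fast, and its output on a constant-colour patch is
  computable by hand, which the tests exploit. Because the statistics are
  bounded and the projection is fixed, feature norms are provably bounded
  for 8-bit input.

## Gated-attention multiple-instance classifier

A slide is a bag X = {x_1..x_M} of patch features with one binary label.
Two fully-connected + ReLU + dropout blocks compress 256 -> 128 -> 128
(only the end dims are fixed by the architecture statement; 256->128->128
is the simplest consistent choice). Gated attention scores each instance

    A_i = softmax_i( w_a (tanh(V_a h_i) * sigmoid(U_a h_i)) ),

with U_a, V_a in R^(64x128), w_a in R^(1x64); the slide embedding is
H = sum_i A_i h_i, classified by a single affine 128->2 head with softmax
(no instance-level clustering loss: only the attention-pooling path is
modelled). The softmax uses max-subtraction; attention therefore is
invariant to any constant shift of the pre-softmax scores, and all slide
outputs are invariant to patch permutation.

Training minimises slide-level cross-entropy, one bag per Adam step
(lr 1e-4, weight decay 1e-5, dropout 0.25, <=200 epochs), with gradients
clipped to global norm 5. All forward/backward passes are explicit NumPy;
the analytic gradients are checked against central finite differences in
the test suite (1e-4 relative, with a floor so finite-difference roundoff
on near-zero entries does not dominate). When a validation split is
supplied, the epoch with the best validation AUROC is kept (ties keep the
earliest epoch; patience 20). The planted-signal recovery experiment
instead trains a fixed 200 epochs on 120 slides without validation
selection: with an easily separable planted texture, validation AUROC
saturates within a few epochs while the attention distribution is still
uniform, so best-AUROC selection would stop before attention concentrates
on the discriminative patches; the attention-enrichment transition occurs
between roughly 200 and 400 epochs under these conditions, so the
experiment trains 400.

## Clinical branch

Preprocessing mirrors routine cohort hygiene: variables missing in more
than one-third of patients are dropped (strictly greater than 1/3);
remaining categorical gaps are imputed with the mode (ties broken
lexicographically), continuous gaps with the median (even counts: mean of
the middle two); schema-declared reference-range binnings (e.g.
white-cell count to decreased/normal/increased at 4 and 10 x10^9/L) apply
before one-hot encoding of multicategory variables; outcome-like
variables (treatment response and kin) are excluded from the design by
schema flag. The full transform is stored in a replayable report and its
replay on the fitting table reproduces the design matrix exactly.

The classifier is a random forest; features are ranked by Gini importance
(mean decrease in impurity, normalised to sum 1) and only positive-
importance features are retained. Hyperparameters (`n_estimators`,
`max_depth`, `min_samples_split`) are tuned by maximising validation
accuracy over seeded uniform draws from [10,300] x [2,20] x [2,20]
(default 100 trials). A sequential model-based sampler could be plugged
in; seeded random search keeps the dependency surface small and is
adequate at this search-space size.

## Compact bilinear pooling fusion

The clinical design vector passes through two affine+ReLU blocks to a
128-d embedding; it and the 128-d slide embedding are fused by compact
bilinear pooling: each vector is count-sketched (random hash + random
sign, drawn once per model from the seed and stored in the checkpoint)
into R^d (default d = 4096) and the sketches are circularly convolved in
the Fourier domain, approximating the full outer product. Standard CBP
post-processing — signed square root, then L2 normalisation (zero maps to
zero) — is on by default, with flags for the plain variant. A constant
bias coordinate is appended to each embedding before sketching, so the
fused representation spans both modalities' linear terms as well as their
pairwise interactions; without it, a purely bilinear form cannot express
"use modality A alone", which measurably costs accuracy at desk-scale
sample sizes. Training is joint end-to-end through both branches (sketch
hashes fixed), with the same optimiser settings as the MIL model; a
`freeze_image` flag trains only the head and clinical branch, running the
frozen image branch in eval mode so no dropout noise enters the head's
training signal. Fusion fits in the experiments warm-start the image
branch from the single-modality MIL fit.

The derivative of the signed square root, 1/(2 sqrt|c|), is floored at
element scale 1e-6; combined with global-norm gradient clipping this
keeps near-zero fused coordinates from producing unbounded steps.

## Evaluation protocol

Patients split 70/10/20 into train/validation/test, stratified by label:
per class, floor(n_c x 0.1) to validation and floor(n_c x 0.2) to test,
remainder to train; repeat r is seeded with `seed + r` (default 10
repeats). Metrics: AUROC (rank statistic with tie-midranks), accuracy,
precision, recall, F1 for the R/R class at threshold 0.5; repeats
aggregate as mean +/- SD with the n-1 denominator. Contingency tables use
the Pearson chi-square; the Yates continuity correction is a caller flag
applied only to 2x2 tables, because published baseline tables mix
corrected and uncorrected rows and the choice must be explicit. Survival
uses the Kaplan-Meier product-limit estimator and the two-group log-rank
test (lifelines).

## Interpretability

Attention scores are min-max normalised to [0,1] (a constant vector maps
to 0.5 — the degenerate case carries no ranking information) and rendered
through a diverging blue-to-red colormap (score 0 -> blue, 1 -> red),
alpha-blended over each patch footprint; pixels outside the grid are
never altered. Nuclear annotations from any external segmenter are
consumed as JSON records (centroid + one of five cell types); per-type
density is centroids-inside-the-tissue-mask per mm^2 given a
microns-per-pixel scale (density is additive over disjoint mask regions).
Group densities are compared with a two-sided Mann-Whitney U
(normal approximation, tie-corrected) — the published comparison names a
p-value but not a test, so the choice is documented here as ours.

## Synthetic cohorts

No public cohort exists for this problem, so the generator produces fully
self-contained study material with known ground truth:

* **Slides.** White-glass background (RGB 250, saturation ~0) with pink
  tissue blobs grown cell-by-cell on the 512-pixel patch grid (default
  3584x2560 slides, 3 blobs x 10 cells ≈ 30 tissue patches). Every tissue
  patch gets dark elliptical nuclei at a Poisson background density
  (12/patch); in R/R slides a Bernoulli fraction `signal_rate_pos`
  (default 0.3, vs 0.0 in controls) of tissue patches instead carries
  `nucleus_density_signal` (default 48/patch, a 4:1 contrast) — the
  planted, recoverable discriminative texture. Planted-patch coordinates
  are saved alongside each slide.
* **Clinical covariates.** A lymphoma-like baseline set (sex, age, stage,
  cell of origin, LDH, white-cell count, extranodal sites, IPI group,
  double expression) with a logistic label model expressed per variable:
  binary covariates are drawn so the group odds ratio equals exp(effect);
  multicategory levels are exponentially tilted by level index;
  continuous covariates get a mean shift of effect x SD in the R/R group
  (the equal-variance Gaussian realisation of a logistic model). Outcome
  variables are never generated. Missingness is MCAR per cell (default
  5%) — real clinical missingness is rarely MCAR, but no mechanism is
  published to emulate.
* **Survival.** Exponential event times with hazard
  h0 x hazard_ratio^label (h0 = ln2/60 per month, hazard ratio 3) and
  administrative censoring at 84 months.
* **Prevalence** defaults to 0.52, the R/R share of the published cohort;
  the label-1 count is exactly round(n x prevalence).

Identical (config, seed) reproduces cohorts byte-for-byte (slide PNGs
included). The generator makes no attempt at realistic histology texture
or stain variation; passing recovery tests therefore demonstrates that
the pipeline's machinery (masking, patching, encoding, attention pooling,
fusion, protocol) is correct and recoverable, not that the learned models
transfer to real tissue.

A deterministic 227-row fixture reconstructs a published DLBCL baseline
table from its printed per-variable marginals (118 R/R vs 109 non-R/R).
Variables are filled independently within each label group because only
marginals are published; all acceptance statistics on the fixture depend
only on those marginals. Rows the published table leaves unaccounted for
(unprinted missing cells) are padded with an explicit Unknown level.

## Experiment problem sizes

The canned experiments (`lymphrisk.experiments`) use these sizes as the
package's standard desk-scale conditions:

* MIL recovery: the generator defaults — 160 slides, ~30 patches each,
  signal rates 0.3/0.0, 4:1 density contrast; 120 train / 40 test.
* Fusion complementarity: 400 patients, 2048x2048 slides (~12 patches),
  signal rates 0.25/0.06 at 30 vs 12 nuclei/patch, clinical effects
  scaled x1.3 — tuned so each modality alone sits near the 0.75-0.8 AUROC
  band; 5 independent seeds.
* Clinical recovery / ranking stability: log-OR 1.0 per SD on 3 of 20
  standardised continuous covariates, 400 patients (Bayes-optimal AUROC
  ~0.89, so a 0.75 recovery bar is meaningful; with binary covariates at
  the same effect size the ceiling would be ~0.72).
* Log-rank calibration: 200 null simulations of 60 vs 60 patients.

## Known limitations

* Pyramidal WSI reading, stain normalisation, and artifact removal are
  out of scope; inputs are flat rasters.
* The neural components are NumPy with hand-written gradients: correct
  (gradient-checked) and adequate at desk scale, but not a GPU training
  stack.
* The nuclear segmenter itself is external; only its output format is
  consumed.
* CBP fusion at a few hundred training patients is sample-hungry: the
  sketched bilinear features dilute a strong single-modality signal
  across many coordinates, and the fused model tracks rather than beats
  the best single modality at these sizes.
* The Table-1 fixture's joint distribution is an artefact of independent
  filling; only its per-variable margins are meaningful.
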