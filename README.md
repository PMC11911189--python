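# lymphrisk

Risk modelling for relapsed/refractory (R/R) diffuse large B-cell
lymphoma (DLBCL) from H&E whole-slide images and baseline clinical data.

Roughly half of DLBCL patients relapse after, or prove refractory to,
first-line chemotherapy, and their prognosis is markedly worse. Flagging
likely R/R patients at diagnosis — from material that already exists in
routine care — would let clinicians intensify monitoring or escalate
therapy early. `lymphrisk` implements that pipeline end to end for
researchers in computational pathology and clinical risk modelling:

* **Slide processing** — HSV-saturation tissue masking (8-bit threshold
  35, median filter + morphological opening), non-overlapping 512x512
  patch grids, HDF5 coordinate stores.
* **Patch encoding** — 256-d features per patch, from a truncated
  residual network (three residual stages, average-pooled) or a
  deterministic statistics-based fixture encoder that needs no weights.
* **Slide classification** — gated-attention multiple-instance learning
  (MIL). A slide is a bag X = {x_1..x_M} of patch features with one
  label; instances are compressed to h_i in R^128 and weighted by

      A_i = softmax_i( w_a (tanh(V_a h_i) * sigmoid(U_a h_i)) ),

  giving the slide embedding H = sum_i A_i h_i, classified by an affine
  head. Trained from slide labels only.
* **Clinical branch** — missingness-aware preprocessing (drop above 1/3
  missing, mode/median imputation, reference-range binning, one-hot),
  random-forest classification with Gini-importance feature selection and
  seeded hyperparameter search.
* **Fusion** — compact bilinear pooling: both 128-d embeddings are
  count-sketched and circularly convolved in the Fourier domain,
  approximating their outer-product interaction; signed-sqrt + L2
  post-normalisation; joint end-to-end training.
* **Evaluation & interpretability** — stratified 7:1:2 splits with
  repeats, AUROC/accuracy/precision/recall/F1, chi-square contingency
  tests, Kaplan-Meier + log-rank survival analysis, blue-to-red attention
  heatmaps, and per-type nuclear densities from external segmenter
  output.
* **Synthetic cohorts** — because no public cohort exists, a generator
  produces H&E-like slides with planted label-discriminative
  high-cellularity patches, Table-1-like covariates under a logistic
  label model, and censored survival times — all byte-reproducible from a
  seed, with ground truth saved for recovery tests.

The neural components are implemented in NumPy with hand-written,
gradient-checked backpropagation; scikit-learn, scipy, lifelines and
scikit-image stand behind the standard steps.

## Worked example

Train the attention-MIL classifier on a synthetic cohort and inspect a
planted-signal slide:

```python
import lymphrisk as lr

config = lr.SyntheticConfig(n_patients=60, slide_width=2048,
                            slide_height=2048, n_blobs=2, blob_cells=6,
                            seed=7)
cohort = lr.build_feature_cohort(config)
split = lr.make_splits(cohort.labels, lr.SplitSpec(n_repeats=1, seed=7))[0]

model = lr.AttentionMIL(
    [cohort.bags[i] for i in split.train], cohort.labels[split.train],
    [cohort.bags[i] for i in split.val], cohort.labels[split.val])
result = model.fit(seed=7, epochs=120)
print(result.summary())

scores = result.predict_proba([cohort.bags[i] for i in split.test])
metrics = lr.compute_metrics(cohort.labels[split.test], scores)
print(f"test AUROC {metrics.auroc:.3f}")
```

Output:

```
Gated-Attention MIL slide classifier
============================================
training slides       44
epochs run            22
selected epoch        0
validation AUROC      1.0000
parameters            66114
test AUROC 0.967
```

The 60-patient cohort plants a high-cellularity texture in 30% of tissue
patches of R/R slides and none of the controls, so a correct
implementation separates the held-out slides almost perfectly — the
validation AUROC saturates immediately (hence the early selected epoch)
and the test AUROC is 0.967; the interesting checks — attention mass concentrating on the
planted patches, behaviour under weaker signals, fusion with clinical
covariates — are run by the acceptance script below. The published
baseline-table statistics are available directly:

```python
from lymphrisk.table1 import reconstruct_table1_fixture, crosstab_counts
fixture = reconstruct_table1_fixture()          # 227 patients, 118 R/R
counts = crosstab_counts(fixture, "double_expression")   # [[40,19],[78,90]]
print(lr.chisq_test(counts))   # (7.987446644450326, 1, 0.0047102797580090335)
```

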