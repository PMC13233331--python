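# Methods

## Problem and model

`hemomil` classifies hematological disease at the patient level from a
*bag* of single-cell embedding vectors — one fixed-width vector per white
blood cell in a peripheral blood smear, as produced by a single-cell
image foundation encoder (default width 768; the encoder itself is
outside this package). Only the bag carries a label: this is
multiple-instance learning (MIL).

The aggregator is a set transformer. Cells are projected into a latent
space (default 512), a learnable aggregation token is prepended, and the
sequence passes through pre-norm transformer blocks (default 2 layers, 8
heads, MLP ratio 2) **without positional encodings** — a smear scan has
no meaningful cell order, and the architecture is permutation invariant
by construction. The aggregation token's output feeds a shared MLP trunk
with two heads:

* **classification** — logits over the 8 coarse diagnostic classes
  (acute leukemia, MDS, MDS/MPN, MPN, lymphoma, plasma cell neoplasm,
  reactive changes, healthy), softmax-normalized;
* **regression** — the patient's hemoglobin on a standardized scale
  (z-scored against the training folds; de-standardized to g/dL for
  reporting).

The joint loss is `cross_entropy + w · squared_error(hb_z)` with
`w = hb_loss_weight` (default 0.5). Squared error on the z-scale keeps
the two terms commensurate; the weight is a tunable with no published
reference value.

**Attention export.** The aggregation token's attention row in the final
block, averaged over heads and renormalized over the cell positions
(dropping the token's self-attention), is the per-cell relevance weight.
It lies on the simplex, is permutation *equivariant*, and for a
singleton bag is exactly `[1.0]`.

**Malignancy triage.** The malignancy probability is the sum of the six
malignant-class probabilities (equivalently `1 − P(reactive) −
P(healthy)`). A biopsy is recommended when it strictly exceeds the
decision threshold (default 0.5). The *aspiration FDR* at a threshold is
the fraction of biopsy-recommended patients whose true condition is
non-malignant. The clinical baseline FDR is computed from per-class
patient counts as `reactive / (reactive + malignant)`: healthy donors
are excluded from the denominator because they are stem-cell donors, not
patients aspirated for diagnosis — with the released test-set
composition (42 reactive, 268 malignant) this gives 42/310 = 13.5%.

## Numerical engine

No tensor/autograd framework is part of the dependency set; the package
carries a small reverse-mode automatic-differentiation engine over numpy
(`hemomil.autograd`): a tape of tensors with broadcast-aware arithmetic,
batched matmul, fused softmax / layer-norm / cross-entropy backward
rules, and Adam. Every gradient rule is verified against central finite
differences in the test suite. Arithmetic is float64 throughout.

Training details: Xavier-uniform initialization from a seeded generator
(member *i* uses `config.seed + i`, so ensemble members differ);
minibatches group bags of equal size so they stack into one array;
early stopping on fold-validation loss (default patience 6, the control
studies use 2–3) restores the best snapshot. A non-finite loss aborts
with a diagnostic rather than silently continuing.

## Cross-validation and ensembling

Patients are dealt into k = 5 folds stratified on the coarse class
(detailed classes can be rarer than k); round-robin dealing keeps
per-fold class counts within one patient of proportionality. Model *i*
trains on folds ≠ *i*. At inference the members' probability vectors are
averaged — the mean of simplex points is a simplex point — as are the
hemoglobin predictions and the (renormalized) attention weights.
Averaging probabilities rather than logits was an open choice; it keeps
the ensemble output interpretable as a probability without a second
normalization.

## Synthetic cohorts

The generator emulates the statistical skeleton the pipeline relies on,
not blood-smear images:

* **cell-type profiles** — isotropic Gaussian clusters in embedding
  space (default 6 types: myeloblast, promyelocyte, neutrophil,
  lymphocyte, monocyte, giant platelet). Centroids are standard-normal
  draws scaled by `separation`; `separation=0` removes all class signal
  (negative control), `separation=5` with unit spread makes types nearly
  separable (positive control).
* **class recipes** — per-class Dirichlet cell-type compositions (total
  concentration 200), with the myeloblast coordinate overridden by an
  explicit uniform latent: acute leukemia 0.20–0.90, MDS 0.02–0.19
  (below the classical 20% blast criterion, so the MDS/acute-leukemia
  boundary is controlled by construction), MDS/MPN 0.02–0.15, others
  ≤ 0.05. This makes the relation between predicted acute-leukemia
  probability and blast ratio a designed ground truth rather than an
  accident of sampling.
* **hemoglobin** — Normal per class, truncated to 3–20 g/dL as a
  physiological plausibility bound; means are ordered plausibly
  (cytopenic classes ~9–10.5, healthy 14, MPN 15) but are placeholders,
  not clinical claims, since no per-class distribution is published.
* **class priors** — default to the released test-set composition
  (46/38/22/48/57/57/42/99 over 409 patients).

What the generator does **not** emulate: real encoder geometry
(anisotropy, manifold structure), staining/domain shift, cell-level
label noise, patient age/sex structure, or correlations between
hemoglobin and composition beyond class identity. Passing the synthetic
controls therefore demonstrates that the pipeline's machinery recovers
a recoverable signal — not that the model reaches any particular
accuracy on real cohorts.

## Control studies and problem sizes

`hemomil.controls` packages two end-to-end studies, also used by the
test suite and the results-reproduction script:

* **positive control** — 400 patients, 200 cells/bag, embedding dim 32,
  6 cell types, separation 5. One stratified fifth (80 patients) is held
  out; a 5-fold ensemble (latent 64, 4 heads, 2 layers) trains on the
  remaining 320 with bags subsampled to 100 cells (composition is
  already well estimated at that depth; inference uses the full bags).
  Expected outcome: held-out accuracy ≥ 0.90, malignant-vs-non-malignant
  AUROC ≥ 0.95, hemoglobin Pearson ≥ 0.8.
* **blast correlation** — Spearman rank correlation between predicted
  acute-leukemia probability and true blast ratio, computed over the
  blast-driven classes (held-out acute-leukemia and MDS patients plus a
  fresh all-acute-leukemia cohort drawn from the same profiles). The
  restriction matters: in the five classes whose blast fraction is
  constitutively ~0 the statistic would measure only rank ties and
  noise, not the designed relation.
* **attention enrichment** — across ≥ 20 tagged acute-leukemia bags,
  mean attention on myeloblasts vs all other cells, one-sided sign
  test.
* **negative control** — 240 patients, 100 cells/bag, separation 0,
  same 5-fold early-stopping protocol. With no signal the
  best-validation model is the prior-matching one, so held-out accuracy
  sits within binomial noise of the class-prior maximum (0.242). Early
  stopping is essential here: trained to convergence without validation,
  a no-signal model collapses to an arbitrary constant prediction and
  its accuracy reflects that class's frequency instead.

These sizes were chosen so the whole suite runs comfortably on a single
CPU core while keeping every class populous enough for stratified
5-fold splitting.

## Numerical choices and edge cases

* ECE: top-label confidence, 10 equal-width bins over (0, 1], empty bins
  contribute 0 — the canonical definition; the binning scheme has no
  published reference.
* AUROC: Mann–Whitney rank statistic, ties at half credit.
* Top-k accuracy: ties broken by the fixed coarse-class order (stable
  sort), so results are deterministic.
* Triage: strictly greater than the threshold; a malignancy probability
  exactly at threshold does not trigger a recommendation.
* Undefined rates (a class never predicted; no acute-leukemia patients
  in a sweep) are reported as missing (NaN), never as 0 or 1.
* Bags larger than `bag_size` are subsampled uniformly without
  replacement; smaller bags pass through unpadded (the aggregator
  accepts any size ≥ 1), avoiding any padding-mask convention.
* Checkpoints store parameters, config, coarse-class order and the
  hemoglobin standardization constants, and refuse to load under a
  different class order.

### Stochasticity of attention placement

Unlike the accuracy/AUROC/hemoglobin/blast-correlation outcomes, which
are stable across training seeds, *where* the aggregation token puts its
attention is partly an accident of initialization. In the synthetic
generator every cell type is an interchangeable Gaussian cluster and
class information is redundant across type proportions (fractions sum
to one), so a trained model can read the blast fraction just as well
from, say, the neutrophil abundance — and single models are observed to
be bimodal, attending either almost always to blasts or almost always
to some other type. Ensemble averaging over five members substantially
stabilizes the blast-enrichment sign test, but occasional training
seeds still produce ensembles whose attention favors a non-blast type
while classifying essentially perfectly. Real smears differ in exactly
the respect the generator idealizes away: blasts are morphological
outliers with no abundant healthy counterpart, which is why attention
concentrates on them much more reliably in practice than in this
symmetric synthetic world.

## Known limitations

* The hierarchy exemplar covers the detailed classes named in routine
  practice (AML, ALL, CLL, ET, PV, CML, MDS, MDS/MPN, multiple myeloma,
  MGUS, …) but is a configuration default, not a complete laboratory
  ontology; users supply their own mapping file for production use.
* The transformer depth/heads/optimizer defaults are declared package
  defaults, not values with an external reference.
* float64 numpy keeps the engine simple and exactly testable but is not
  competitive in speed with GPU frameworks; the package targets method
  validation and desk-scale experiments, not large-scale training.
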