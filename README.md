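# hemomil

Attention-based multiple-instance learning for hematological disease
triage from peripheral blood smears.

## The problem

A peripheral blood smear yields hundreds of single-cell images per
patient, but the diagnosis (acute leukemia, MDS, MDS/MPN, MPN, lymphoma,
plasma cell neoplasm, reactive changes, healthy) is a property of the
patient, not of any one cell. `hemomil` treats each patient as a **bag**
of single-cell embedding vectors $\{x_1,\dots,x_n\}$, $x_i \in
\mathbb{R}^d$ (as produced by a hematology image foundation encoder,
default $d=768$), and learns

$$p(y \mid \{x_i\}) = \mathrm{softmax}\big(f_\theta(\mathrm{agg}(\{x_i\}))\big),$$

where `agg` is a permutation-invariant transformer that pools the cells
through a learnable aggregation token. The same trunk regresses the
patient's hemoglobin as an auxiliary task. The aggregation token's
attention row $a \in \Delta^{n-1}$ is exported per cell: it identifies
the diagnostically relevant cells (e.g. myeloblasts in acute leukemia).

For triage, the **malignancy probability** is the summed probability of
the six malignant classes,
$P_{\text{mal}} = 1 - p(\text{reactive}) - p(\text{healthy})$;
a bone marrow biopsy is recommended when $P_{\text{mal}}$ exceeds a
decision threshold (default 0.5). Sweeping the threshold trades
acute-leukemia sensitivity against the **aspiration FDR** — the fraction
of biopsy-recommended patients whose condition turns out non-malignant,
i.e. the unnecessary-biopsy rate.

The package contains the full pipeline: a configurable three-level
diagnostic label hierarchy, a synthetic cohort generator with
class-conditioned cell-type mixtures and a controllable blast-fraction
latent, the set-transformer model (on a self-contained numpy autograd
engine — no deep-learning framework required), stratified 5-fold
cross-validation with probability-averaged ensembling, the triage and
evaluation suite (confusion analysis, top-k accuracy, expected
calibration error, AUROC, threshold sweeps, hemoglobin agreement), and
per-patient attention explanations. See `docs/methods.md` for the model
and its assumptions.

## Worked example

Train a small 5-fold ensemble on a synthetic cohort of 160 patients
(100 cells per bag, embedding dim 32) and evaluate on a held-out fifth:

```bash
python examples/02_train_and_evaluate.py
```

```
held-out patients     : 32
accuracy              : 1.000
top-2 accuracy        : 1.000
malignancy AUROC      : 1.000
calibration error ECE : 0.135
hemoglobin Pearson r  : 0.708  (MAE 1.34 g/dL)
```

Accuracy far above the 0.24 majority-class rate shows the aggregator
recovers the class signal from cell composition alone; the malignancy
AUROC near 1 means malignant and non-malignant patients are almost
perfectly ranked by $P_{\text{mal}}$; the hemoglobin correlation shows
the auxiliary regression head tracks the measured values to within
about 1.3 g/dL on this small cohort.

The other examples cover cohort simulation
(`01_simulate_cohort.py`), triage threshold sweeps against the 13.5%
clinical baseline FDR (`03_triage_threshold_sweep.py`), and cell-level
attention reports (`04_explain_attention.py`). The same stages are
available as a CLI: `hemomil simulate | train | predict | sweep |
evaluate | explain`.

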