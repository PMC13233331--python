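"""Malignancy triage: threshold sweep and the clinical baseline.

The malignancy probability is the summed probability of the six
malignant classes; a biopsy is recommended when it exceeds the decision
threshold.  Sweeping the threshold trades acute-leukemia sensitivity
against the aspiration FDR (the unnecessary-biopsy rate).  The clinical
baseline FDR from the released test-set composition is 42 reactive /
310 aspirated = 13.5%.
"""

import numpy as np

import hemomil as hm
from hemomil.simulate import RELEASED_TEST_SET_COUNTS

h = hm.default_hierarchy()

baseline = hm.clinical_baseline_fdr(RELEASED_TEST_SET_COUNTS, h)
print(f"clinical baseline aspiration FDR: {100 * baseline:.1f}%")

# noisy but informative synthetic malignancy scores for illustration
rng = np.random.default_rng(0)
classes = rng.choice(
    list(RELEASED_TEST_SET_COUNTS),
    p=hm.released_test_set_priors(h), size=409,
)
mal_mask = np.array([h.malignant_flags[x] for x in h.coarse_classes])
probs = []
for c in classes:
    # draw a malignancy score centered high for malignant patients, then
    # spread it uniformly over the malignant / benign classes
    score = np.clip(
        rng.normal(0.75 if h.malignant_flags[c] else 0.25, 0.18), 0.001, 0.999
    )
    probs.append(np.where(mal_mask, score / 6, (1 - score) / 2))

result = hm.threshold_sweep(probs, list(classes), h)
table = result.table[result.table["threshold"].isin([0.2, 0.4, 0.5, 0.6, 0.8])]
print("\nthreshold  sensitivity  specificity  aspiration FDR  AL sensitivity")
for _, r in table.iterrows():
    print(f"  {r['threshold']:.2f}      {r['malignancy_sensitivity']:.3f}       "
          f"{r['malignancy_specificity']:.3f}        {r['aspiration_fdr']:.3f}"
          f"          {r['acute_leukemia_sensitivity']:.3f}")
print(
    f"\nlargest threshold keeping every acute leukemia flagged: "
    f"{result.best_full_al_sensitivity_threshold:.2f} "
    f"(FDR there {result.fdr_at_best:.3f})"
)
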