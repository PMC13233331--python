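"""Cell-level attention explanation for one synthetic patient.

Trains a 5-fold ensemble (about a minute), then explains an
acute-leukemia bag: the report lists the most-attended cells with their
singleton-bag class calls.  With ground-truth cell-type tags we can
check that myeloblasts — the diagnostic cells for acute leukemia —
receive more attention than the rest of the smear.
"""

import numpy as np

import hemomil as hm

h = hm.default_hierarchy()
manifest, bags = hm.generate_cohort(
    n_patients=160, n_cells=100, seed=21, embedding_dim=32
)
config = hm.ModelConfig(
    embedding_dim=32, bag_size=100, latent_dim=64, n_heads=4, n_layers=2, seed=2
)
ensemble = hm.train_ensemble(
    manifest, bags, config, hm.TrainParams(epochs=10, k=5, patience=3, seed=2)
)

al_rows = manifest.index[manifest["coarse_class"] == "acute leukemia"]
bag = bags[al_rows[0]]
report = hm.explain(ensemble, bag, h)
print(report.summary(m=5))
print(
    "true cell types of the top-5 cells:",
    [bag.cell_types[j] for j in hm.top_cells(report, 5)],
)

is_blast = np.asarray(bag.cell_types) == "myeloblast"
a = report.attention_weights
print(
    f"\nmean attention on myeloblasts     : {a[is_blast].mean():.5f}"
    f"\nmean attention on all other cells : {a[~is_blast].mean():.5f}"
)
print("(higher on myeloblasts = the model attends to the diagnostic cells)")
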