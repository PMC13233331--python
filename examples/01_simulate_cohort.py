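"""Generate a synthetic patient cohort and inspect its structure.

Each patient is a bag of single-cell embedding vectors plus a manifest
row; the class mix follows the released test-set composition (409
patients across 8 coarse diagnostic classes).
"""

import hemomil as hm

h = hm.default_hierarchy()
manifest, bags = hm.generate_cohort(
    n_patients=409, n_cells=200, seed=7, embedding_dim=32
)

print(f"patients: {len(manifest)}, cells/bag: {bags[0].n_cells}, "
      f"embedding dim: {bags[0].embeddings.shape[1]}")
print("\nclass composition (counts):")
print(manifest["coarse_class"].value_counts().to_string())
print("\nmean blast ratio by class (acute leukemia high, MDS < 0.20):")
print(manifest.groupby("coarse_class")["blast_ratio"].mean().round(3).to_string())
print("\nmean hemoglobin by class, g/dL (cytopenic classes low):")
print(manifest.groupby("coarse_class")["hemoglobin"].mean().round(1).to_string())
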