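"""Screen FANS reference samples with the PCA-based maxSD classifier.

Plants a failed sort: one donor whose "purified fractions" are all the same
unsorted mixture.  Those samples sit at the centre of the principal-component
space, far from their labelled fraction's cluster, so the donor's median
maxSD (distance from the labelled fraction mean in fraction SDs, maximised
over PC1/PC2) crosses the failed-sort threshold of 5.
"""

import numpy as np

import neurodeconv as nd

atoms = nd.generate_atomic_profiles(seed=1)
# array-run scale: every sorted sample, before any QC exclusions
ref, sheet = nd.sample_reference(
    atoms,
    n_per_fraction={"NeuNPos": 42, "NeuNNeg/SOX10Pos": 39, "NeuNNeg/SOX10Neg": 33},
    noise_sd=0.01,
    seed=2,
)

# donor ind001's three fractions are replaced by the same unsorted mixture
rng = np.random.default_rng(5)
data = ref.data.copy()
centroid = data.mean(axis=1)
for sid in sheet.loc[sheet["individual_id"] == "ind001", "sample_id"]:
    data[sid] = np.clip(centroid + rng.normal(0, 0.01, len(centroid)), 0, 1)

report = nd.fans_qc(nd.MethylationMatrix(data), sheet)
flagged = report.individuals[report.individuals["sort_failed"]]
print("failed-sort individuals:")
print(flagged.to_string(index=False))
retained = report.samples["retained"]
print(f"\nsamples retained: {int(retained.sum())}/{len(retained)}")
print("dropped samples:", ", ".join(report.samples.loc[~retained, "sample_id"]))
print()
print("All three of the planted donor's samples are removed.  The 2-SD")
print("retention test also trims a few borderline samples at the edge of")
print("their fraction's cluster - deliberate conservatism when curating a")
print("reference whose per-fraction means anchor all downstream estimates.")
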