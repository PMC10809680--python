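"""Generate a synthetic FANS-style reference dataset.

Builds the default latent model (six atomic cell types with planted
type-specific and lineage-specific differentially methylated sites, effect
size 0.4 on the beta scale) and samples the ten purified nuclei fractions
with measurement noise, exactly as a sorted-nuclei reference study would
deliver them: a sites x samples beta matrix plus a sample sheet.
"""

import neurodeconv as nd

atoms = nd.generate_atomic_profiles(seed=1)
ref, sheet = nd.sample_reference(atoms, noise_sd=0.02, seed=2)

print(f"atomic types : {', '.join(atoms.atomic_labels)}")
print(f"lineages     : {', '.join(atoms.lineages)}")
print(f"beta matrix  : {ref.n_sites} sites x {ref.n_samples} samples")
print("samples per fraction:")
print(sheet["fraction_label"].value_counts().to_string())
print()
print("Each fraction is a mixture of the latent atomic types, so the")
print("overlapping NeuNPos / SATB2Pos pair shares most of its cells while")
print("remaining distinguishable through the excitatory sub-populations.")
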