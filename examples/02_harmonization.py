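"""Harmonize merged multi-batch data and verify it with PCA.

Before harmonization, cohort-of-origin dominates the leading principal
components of the hypervariable probes; quantile normalization + ComBat
removes that structure.  The printed R-squared is the share of PC1
variance explained by batch labels - near 1 means batches separate,
near 0 means they mix.
"""

from methbench import (SimulationConfig, generate_study, harmonize,
                       merge_batches, pca_batch_diagnostic)

cfg = SimulationConfig(n_probes=800, n_signal_probes=0, effect_size_m=0.0,
                       samples_per_batch=[50] * 8, batch_mean_shift_sd=1.5,
                       seed=3)
merged = merge_batches(generate_study(cfg)[0])

before = pca_batch_diagnostic(merged)
harmonized, model = harmonize(merged)
after = pca_batch_diagnostic(harmonized)

print(f"hypervariable probes used: {before['n_hypervariable']}")
print(f"batch R^2 on PC1 before harmonization: {before['r2_pc1']:.3f}")
print(f"batch R^2 on PC1 after QN + ComBat:    {after['r2_pc1']:.3f}")
print(f"ComBat converged: {model.converged} "
      f"({model.n_iterations} EB iterations total)")
print("a drop from ~1 to ~0 means cohort structure no longer dominates")
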