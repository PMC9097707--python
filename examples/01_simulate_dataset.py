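"""Generate a synthetic multi-generation WGBS experiment.

Builds a small genome annotation and a count matrix for 54 samples (controls
plus four stressor lines at generations F1/F2/F4, three replicates each),
with planted differentially methylated positions recorded in a truth table.
"""

import tgmeth

config = tgmeth.SimulationConfig(n_cpgs=20_000, master_seed=1)
annotation = tgmeth.simulate_annotation(config)
matrix, sheet, truth = tgmeth.simulate_experiment(config, annotation)

pct = tgmeth.call_methylated_sites(matrix)
controls = sheet.samples_for(treatment="control")
ctrl_mean = pct[[matrix.samples.index(s) for s in controls]].mean()

print(f"{matrix.n_sites} CpGs x {matrix.n_samples} samples, "
      f"{len(annotation.genes)} genes")
print(f"mean coverage: {matrix.total.mean():.2f}x  "
      f"(target {config.coverage_mean}x)")
print(f"control samples call {ctrl_mean:.2f}% of CpGs methylated "
      "(sparse, invertebrate-like methylation)")
print(f"truth table: {len(truth)} planted DMPs, of which "
      f"{(truth.persistence_class == 'transgenerational').sum()} persist "
      "through F2 and F4")
# The truth table is the ground reference for recovery benchmarks: every
# planted site lists its direction, effect size and persistence class.
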