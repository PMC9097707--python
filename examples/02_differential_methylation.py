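"""Per-generation differential methylation testing for one stressor.

Applies the standard filter chain (coverage >= 5 in every sample of the
comparison, median-coverage normalisation, SD >= 0.5 variability filter),
then runs the beta-binomial Wald test of each generation's 3 cases against
the pooled 9 controls, with BH adjustment per generation.
"""

import tgmeth

config = tgmeth.SimulationConfig(n_cpgs=20_000, master_seed=1)
annotation = tgmeth.simulate_annotation(config)
matrix, sheet, truth = tgmeth.simulate_experiment(config, annotation)

design = tgmeth.ComparisonDesign.from_samplesheet(sheet, "microcystin")
prepared = tgmeth.prepare_comparison(matrix, design)
print(f"{prepared.n_sites} of {matrix.n_sites} CpGs testable after filters")

for gen in ("F1", "F2", "F4"):
    res = tgmeth.test_generation(prepared, design.case_samples[gen],
                                 design.control_pool)
    dmps = tgmeth.call_dmps(res, fdr=0.05)
    hyper = sum(1 for d in dmps.sites.values() if d == "hyper")
    print(f"{gen}: {len(dmps)} DMPs at 5% FDR "
          f"({hyper} hyper, {len(dmps) - hyper} hypo)")
# Each generation's DMP count mixes direct effects (F1) with inherited ones
# (F2/F4); the next example intersects them into transgenerational calls.
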