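"""Transgenerational DMP calling and its permutation support.

Intersects the per-generation DMP sets, reports the persistence fraction
(share of F1 DMPs still differential in F2 and F4), checks hypo/hyper sign
consistency, and tests the three-way overlap against random same-size CpG
sets drawn from the tested universe.
"""

import numpy as np

import tgmeth

config = tgmeth.SimulationConfig(n_cpgs=20_000, master_seed=1)
annotation = tgmeth.simulate_annotation(config)
matrix, sheet, truth = tgmeth.simulate_experiment(config, annotation)

design = tgmeth.ComparisonDesign.from_samplesheet(sheet, "microcystin")
prepared = tgmeth.prepare_comparison(matrix, design)
results = {g: tgmeth.test_generation(prepared, design.case_samples[g],
                                     design.control_pool)
           for g in ("F1", "F2", "F4")}
dmps = {g: tgmeth.call_dmps(r) for g, r in results.items()}

part = tgmeth.intersect_generations(dmps["F1"], dmps["F2"], dmps["F4"])
print("Venn regions:", part.region_counts())
print(f"persistence: {tgmeth.persistence_fraction(part)}% of the "
      f"{part.f1_total} F1 DMPs remain differential in F2 and F4")

signs = tgmeth.check_sign_consistency(part, results)
print(f"sign consistency across generations: "
      f"{100 * signs.attrs['fraction_consistent']:.0f}%")

overlap = tgmeth.overlap_permutation_test(
    [dmps[g].keys() for g in dmps], prepared.site_keys(),
    n_perm=1000, rng=np.random.default_rng(0))
print(f"overlap permutation test: observed {overlap['observed']} shared "
      f"sites, null mean {overlap['null_mean']:.2f}, p = "
      f"{overlap['p_value']:.4g}")

planted = tgmeth.transgenerational_truth(truth, "microcystin")
tested = planted & set(prepared.site_keys())
print(f"recovered {len(part.center & tested)} of {len(tested)} planted "
      "transgenerational DMPs that survived the filters")
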