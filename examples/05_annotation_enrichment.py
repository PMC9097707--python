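"""Positional annotation and GO enrichment of transgenerational DMPs.

Classifies DMPs into exon / intron / intergenic against the genome-wide CpG
background, summarises within-gene clustering, and runs one-sided Fisher
GO-term enrichment of the DMP-carrying genes.
"""

import pandas as pd

import tgmeth

config = tgmeth.SimulationConfig(n_cpgs=20_000, master_seed=1)
annotation = tgmeth.simulate_annotation(config)
matrix, sheet, truth = tgmeth.simulate_experiment(config, annotation)

design = tgmeth.ComparisonDesign.from_samplesheet(sheet, "microcystin")
prepared = tgmeth.prepare_comparison(matrix, design)
dmps = {g: tgmeth.call_dmps(tgmeth.test_generation(
    prepared, design.case_samples[g], design.control_pool))
    for g in ("F1", "F2", "F4")}
center = tgmeth.intersect_generations(*dmps.values()).center
center_df = pd.DataFrame(sorted(center), columns=["chrom", "pos"])

dist = tgmeth.genomic_distribution(center_df, matrix.sites, annotation)
print(f"transgenerational DMPs in gene bodies: "
      f"{dist['dmp']['genebody_pct']:.1f}% "
      f"(background CpGs: {dist['background']['genebody_pct']:.1f}%)")
print(f"exon share of gene-body DMPs: "
      f"{dist['dmp']['exon_share_of_genebody_pct']:.1f}%")

assigned = tgmeth.assign_nearest_gene(center_df, annotation)
clustering = tgmeth.gene_dmp_clustering(assigned)
print(f"genes with >= 2 DMPs: {clustering['fraction_multi_pct']:.0f}% "
      f"(median intra-gene distance "
      f"{clustering['median_pairwise_distance_bp']} bp)")

study = set(assigned.loc[assigned["distance"] == 0, "gene_id"].dropna())
tested_df = pd.DataFrame(prepared.site_keys(), columns=["chrom", "pos"])
bg_assigned = tgmeth.assign_nearest_gene(tested_df, annotation)
background = set(bg_assigned.loc[bg_assigned["distance"] == 0,
                                 "gene_id"].dropna())
enrich = tgmeth.go_enrichment(study & background, background,
                              annotation.go_map)
print("top GO terms:")
print(enrich.head(5).to_string(index=False))
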