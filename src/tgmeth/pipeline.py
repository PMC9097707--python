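"""End-to-end orchestration: simulate -> QC -> test -> transgenerational calls
-> overlap permutation -> annotation -> GO enrichment -> fitness -> summary.

Stages write TSV/JSON artifacts into the output directory together with a
manifest (config, seed, version) that fully determines every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (assign_nearest_gene, gene_dmp_clustering, genomic_distribution,
                       go_enrichment)
from .config import GENERATIONS, SimulationConfig, stage_rng
from .dm import (ComparisonDesign, call_dmps, prepare_comparison, qc_samples,
                 test_generation)
from .fitness import add_fitness, fitness_effects
from .io import (write_dmp_table, write_gff3, write_go_map, write_report,
                 write_samplesheet)
from .matrix import MethylationMatrix
from .resampling import cross_stressor_overlap_test, overlap_permutation_test
from .simulate import (simulate_annotation, simulate_experiment,
                       simulate_lifehistory, transgenerational_truth)
from .transgen import (alternative_two_stage, check_sign_consistency,
                       cross_stressor_overlap, effect_size_pairs,
                       intersect_generations, persistence_fraction,
                       strategy_concordance)

log = logging.getLogger(__name__)


def _genes_with_sites(sites: pd.DataFrame, annotation) -> set[str]:
    assigned = assign_nearest_gene(sites, annotation)
    inside = assigned[(assigned["distance"] == 0) & assigned["gene_id"].notna()]
    return set(inside["gene_id"])


def analyse_treatment(matrix: MethylationMatrix, design: ComparisonDesign,
                      fdr: float = 0.05, min_total: int = 5, sd_min: float = 0.5,
                      d0: float = 20.0, method: str = "wald",
                      n_overlap_perm: int = 1000,
                      rng: np.random.Generator | None = None) -> dict:
    """Per-generation tests, Venn intersection and overlap permutation test
    for a single treatment.  Returns all intermediate objects."""
    prepared = prepare_comparison(matrix, design, min_total=min_total,
                                  sd_min=sd_min)
    results, dmps = {}, {}
    for gen in design.generations:
        res = test_generation(prepared, design.case_samples[gen],
                              design.control_pool, d0=d0, method=method)
        results[gen] = res
        dmps[gen] = call_dmps(res, fdr=fdr, label=f"{design.treatment}:{gen}")
    partition = intersect_generations(dmps["F1"], dmps["F2"], dmps["F4"])
    universe = prepared.site_keys()
    overlap = overlap_permutation_test(
        [dmps[g].keys() for g in GENERATIONS], universe,
        n_perm=n_overlap_perm, rng=rng) if all(len(dmps[g]) for g in GENERATIONS) \
        else {"observed": len(partition.center), "p_value": 1.0,
              "null_mean": float("nan"), "null_sd": float("nan"),
              "n_perm": n_overlap_perm}
    return {"prepared": prepared, "results": results, "dmps": dmps,
            "partition": partition, "universe": universe, "overlap": overlap}


def run_pipeline(config: SimulationConfig, seed: int | None = None,
                 outdir: str | Path = "tgmeth_out", fdr: float = 0.05,
                 n_overlap_perm: int = 1000, write_artifacts: bool = True,
                 n_boot: int = 2000) -> dict:
    """Execute the full synthetic-study pipeline; returns the summary dict."""
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(),
                                             "master_seed": int(seed)})
    config.validate()
    outdir = Path(outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("simulating annotation and experiment (seed=%d)", config.master_seed)
    annotation = simulate_annotation(config)
    matrix, sheet, truth = simulate_experiment(config, annotation)
    qc = qc_samples(matrix, sheet)

    summary: dict = {"seed": config.master_seed, "n_sites": matrix.n_sites,
                     "n_samples": matrix.n_samples, "treatments": {}}
    summary["qc"] = {
        "mean_coverage": {s: float(m) for s, m in
                          zip(qc["sample_id"], qc["mean_coverage"])},
        "n_flagged": int((qc["flag_low_coverage"] | qc["flag_meth_outlier"]).sum()),
    }
    ctrl_ids = sheet.samples_for(treatment="control")
    from .dm import call_methylated_sites
    pct = call_methylated_sites(matrix.subset_samples(ctrl_ids))
    summary["control_pct_methylated_mean"] = float(np.mean(pct))

    transgen_sets = {}
    tested_universes: dict[str, set] = {}
    all_sites = matrix.sites
    for i, treatment in enumerate(sorted(config.stressors)):
        design = ComparisonDesign.from_samplesheet(sheet, treatment)
        rng = stage_rng(config.master_seed, "overlap", extra=i)
        art = analyse_treatment(matrix, design, fdr=fdr,
                                n_overlap_perm=n_overlap_perm, rng=rng)
        dmps, partition = art["dmps"], art["partition"]
        transgen_sets[treatment] = dmps["F1"].__class__(
            sites={k: dmps["F1"].sites.get(k, "hyper") for k in partition.center},
            label=f"{treatment}:transgenerational")

        signs = check_sign_consistency(partition, art["results"])
        pairs = effect_size_pairs(art["results"]["F1"], art["results"]["F4"],
                                  partition.center)
        alt = alternative_two_stage(art["prepared"], design)
        concord = strategy_concordance(transgen_sets[treatment], alt)

        # truth recovery (over sites that survived the filters, i.e. testable)
        planted = transgenerational_truth(truth, treatment)
        tested = set(art["universe"])
        tested_universes[treatment] = tested
        planted_tested = planted & tested
        called = partition.center
        recall = (100.0 * len(called & planted_tested) / len(planted_tested)
                  if planted_tested else float("nan"))
        jacc = (len(called & planted_tested) / len(called | planted_tested)
                if (called or planted_tested) else float("nan"))

        # positional + functional annotation of the transgenerational set
        center_df = pd.DataFrame(sorted(called), columns=["chrom", "pos"])
        dist = genomic_distribution(center_df, all_sites, annotation) \
            if len(center_df) else None
        clustering = gene_dmp_clustering(assign_nearest_gene(center_df, annotation)) \
            if len(center_df) else None
        background_genes = _genes_with_sites(
            pd.DataFrame(sorted(tested), columns=["chrom", "pos"]), annotation)
        study_genes = (_genes_with_sites(center_df, annotation)
                       if len(center_df) else set()) & background_genes
        enrichment = (go_enrichment(study_genes, background_genes,
                                    annotation.go_map)
                      if study_genes and background_genes else pd.DataFrame())

        entry = {
            "n_tested_sites": len(tested),
            "dmps_per_generation": {g: len(dmps[g]) for g in GENERATIONS},
            "venn": partition.region_counts(),
            "transgenerational": len(partition.center),
            "persistence_pct": (persistence_fraction(partition)
                                if partition.f1_total else None),
            "sign_consistency_fraction": signs.attrs["fraction_consistent"],
            "effect_pair_correlation": pairs.attrs["correlation"],
            "overlap_permutation_p": art["overlap"]["p_value"],
            "two_stage_n": len(alt),
            "two_stage_concordance_pct": concord,
            "planted_transgenerational": len(planted),
            "planted_transgenerational_tested": len(planted_tested),
            "recall_pct": recall,
            "jaccard_vs_truth": jacc,
            "genomic_distribution": dist,
            "clustering": clustering,
            "top_go_terms": (enrichment.head(10).to_dict("records")
                             if len(enrichment) else []),
        }
        summary["treatments"][treatment] = entry

        if write_artifacts:
            for gen in GENERATIONS:
                write_dmp_table(art["results"][gen],
                                outdir / f"dm_{treatment}_{gen}.tsv")
            write_dmp_table(signs, outdir / f"signs_{treatment}.tsv")
            write_dmp_table(pairs, outdir / f"effect_pairs_{treatment}.tsv")
            if len(enrichment):
                write_dmp_table(enrichment, outdir / f"go_{treatment}.tsv")

    # cross-stressor overlap table + permutation test over the union of the
    # per-treatment tested universes
    if len(transgen_sets) >= 2:
        summary["cross_stressor_overlap"] = cross_stressor_overlap(transgen_sets)
        union_universe = sorted(set().union(*tested_universes.values()))
        rng = stage_rng(config.master_seed, "overlap", extra=99)
        summary["cross_stressor_overlap_p"] = {
            pair: res["p_value"] for pair, res in cross_stressor_overlap_test(
                transgen_sets, union_universe, n_perm=min(n_overlap_perm, 1000),
                rng=rng).items()}

    # fitness
    lh = simulate_lifehistory(config)
    lh = add_fitness(lh)
    effects = fitness_effects(lh, n_boot=n_boot,
                              rng=stage_rng(config.master_seed, "bootstrap"))
    summary["fitness_effects"] = effects.to_dict("records")

    if write_artifacts:
        write_samplesheet(sheet, outdir / "samplesheet.csv")
        write_gff3(annotation, outdir / "annotation.gff3")
        write_go_map(annotation.go_map, outdir / "go_map.tsv")
        write_dmp_table(truth, outdir / "truth_table.tsv")
        write_dmp_table(qc, outdir / "qc.tsv")
        write_dmp_table(lh, outdir / "lifehistory.tsv")
        write_dmp_table(effects, outdir / "fitness_effects.tsv")
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.master_seed,
            "tgmeth_version": __version__,
        }
        write_report(manifest, outdir / "manifest.json")
        write_report(summary, outdir / "summary.json")
    return summary
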