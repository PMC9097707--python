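"""Synthetic WGBS experiment generator with planted, persistence-controlled DMPs.

The generator emulates a clonal multi-generation exposure design: control and
stressor lines sampled at generations F1, F2 and F4 (three replicates each),
whole-genome CpG counts at low mean coverage with strong site-level
(mappability-like) heterogeneity, a two-component site methylation mixture
(most sites near zero, a small methylated component enriched in gene bodies
and exons), stressor-specific hypo-/hypermethylated planted DMPs of which a
configurable fraction persists across generations, and a demethylating-drug
treatment modelled as global multiplicative hypomethylation in F1 with
near-complete resetting afterwards.

Every stage draws from an independently derived child stream of the master
seed (see :func:`tgmeth.config.stage_rng`), so outputs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import classify_sites
from .config import (GENERATIONS, PERSISTENCE_CLASSES, TREATMENT_EXPERIMENT,
                     SimulationConfig, stage_rng)
from .matrix import Gene, GenomeAnnotation, MethylationMatrix, SampleSheet

# relative weights of the non-persistent classes once a site is not
# transgenerational: most induced marks reset after F1
_NONPERSISTENT_WEIGHTS = {"F1-only": 0.6, "F1F2": 0.2, "F1F4": 0.2}

TREATMENT_CODE = {"control": "C", "microcystin": "L", "temperature": "T",
                  "zinc": "Z", "azacytidine": "A"}


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _split_even(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _allocate(total: int, weights: np.ndarray, minimum: int = 1) -> np.ndarray:
    """Allocate ``total`` integer units across len(weights) parts, each >= minimum."""
    k = len(weights)
    if total < k * minimum:
        raise ValueError("sizing error: not enough room to allocate intervals")
    spare = total - k * minimum
    raw = weights / weights.sum() * spare
    out = np.floor(raw).astype(int) + minimum
    # distribute the remainder deterministically to the largest fractional parts
    rem = total - out.sum()
    frac_order = np.argsort(-(raw - np.floor(raw)), kind="mergesort")
    out[frac_order[:rem]] += 1
    return out


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Generate non-overlapping gene models with exons and a synthetic GO map."""
    config.validate()
    rng = stage_rng(config.master_seed, "annotation")
    chroms = _chrom_names(config.n_chromosomes)
    cpgs_per_chrom = _split_even(config.n_cpgs, config.n_chromosomes)
    chrom_sizes = {c: n * config.cpg_spacing + config.cpg_spacing
                   for c, n in zip(chroms, cpgs_per_chrom)}

    genes: list[Gene] = []
    go_map: dict[str, set[str]] = {}
    if config.n_genes > 0:
        genes_per_chrom = _split_even(config.n_genes, config.n_chromosomes)
        gene_no = 0
        for chrom, g in zip(chroms, genes_per_chrom):
            if g == 0:
                continue
            length = chrom_sizes[chrom]
            genic_total = int(round(config.genic_fraction * length))
            min_gene = max(2 * config.exons_per_gene, 10)
            if genic_total < g * min_gene or length - genic_total < g + 1:
                raise ValueError(
                    "sizing error: n_genes x mean gene length exceeds chromosome")
            gene_lens = _allocate(genic_total, rng.uniform(0.7, 1.3, g), min_gene)
            gap_lens = _allocate(length - genic_total, rng.uniform(0.5, 1.5, g + 1), 1)
            cursor = 0
            for gi in range(g):
                cursor += gap_lens[gi]
                start = cursor + 1  # 1-based inclusive
                end = cursor + gene_lens[gi]
                cursor = end
                gene_no += 1
                gid = f"gene{gene_no:05d}"
                genes.append(Gene(gene_id=gid, chrom=chrom, start=start, end=end,
                                  strand="+" if rng.random() < 0.5 else "-",
                                  exons=_make_exons(rng, start, end, config)))
        vocab = [f"GO:{i + 1:07d}" for i in range(max(10, config.n_genes // 5))]
        for g_obj in genes:
            k = int(rng.integers(1, 11))
            k = min(k, len(vocab))
            go_map[g_obj.gene_id] = set(rng.choice(vocab, size=k, replace=False))
    return GenomeAnnotation(genes=genes, go_map=go_map, chrom_sizes=chrom_sizes)


def _make_exons(rng: np.random.Generator, start: int, end: int,
                config: SimulationConfig) -> list[tuple[int, int]]:
    length = end - start + 1
    n_ex = config.exons_per_gene
    if n_ex == 1:
        return [(start, end)]
    exon_total = max(n_ex, int(round(config.exon_fraction_of_gene * length)))
    exon_total = min(exon_total, length - (n_ex - 1))
    exon_lens = _allocate(exon_total, rng.uniform(0.5, 1.5, n_ex), 1)
    intron_lens = _allocate(length - exon_total, rng.uniform(0.5, 1.5, n_ex - 1), 1)
    exons = []
    cursor = start
    for i in range(n_ex):
        exons.append((cursor, cursor + int(exon_lens[i]) - 1))
        cursor += int(exon_lens[i])
        if i < n_ex - 1:
            cursor += int(intron_lens[i])
    return exons


def simulate_cpg_sites(config: SimulationConfig) -> pd.DataFrame:
    """Jittered-grid CpG positions, sorted by (chrom, pos)."""
    rng = stage_rng(config.master_seed, "site_levels", extra=0)
    chroms = _chrom_names(config.n_chromosomes)
    per_chrom = _split_even(config.n_cpgs, config.n_chromosomes)
    frames = []
    half = max(1, config.cpg_spacing // 4)
    for chrom, n in zip(chroms, per_chrom):
        grid = config.cpg_spacing // 2 + config.cpg_spacing * np.arange(n)
        jitter = rng.integers(-half, half + 1, size=n)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": grid + jitter}))
    sites = pd.concat(frames, ignore_index=True)
    sites["pos"] = sites["pos"].clip(lower=1)
    return sites


def _build_sample_sheet(config: SimulationConfig) -> SampleSheet:
    stressors = sorted(config.stressors)
    experiments = sorted({TREATMENT_EXPERIMENT[s] for s in stressors}) or ["T1"]
    rows = []
    for exp in experiments:
        for gen in GENERATIONS:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{exp}_C{gen[1]}_B{r}", exp, "control", gen, f"B{r}"))
    for s in stressors:
        exp = TREATMENT_EXPERIMENT[s]
        code = TREATMENT_CODE.get(s, s[0].upper())
        for gen in GENERATIONS:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{exp}_{code}{gen[1]}_B{r}", exp, s, gen, f"B{r}"))
    frame = pd.DataFrame(rows, columns=["sample_id", "experiment", "treatment",
                                        "generation", "clone_line"])
    return SampleSheet(frame)


def _plant_dmps(config: SimulationConfig, sites: pd.DataFrame,
                p_site: np.ndarray, meth_mask: np.ndarray,
                genic_weights: np.ndarray) -> pd.DataFrame:
    """Choose planted DMP sites, directions, effects and persistence classes.

    Hypomethylated DMPs are always methylated-component sites (one cannot
    hypomethylate a ~0% site): they are drawn from the existing methylated
    pool first and, if the desk-scale pool is too small, additional sites are
    converted into the methylated component using the same genic-enrichment
    weights (``p_site`` and ``meth_mask`` are updated in place).  In a
    genome-scale run the pool is never limiting.
    """
    rng = stage_rng(config.master_seed, "planting")
    a_hi, b_hi = config.high_meth_beta_params
    taken = np.zeros(len(sites), dtype=bool)
    rows = []
    for stressor in sorted(config.stressors):
        sc = config.stressors[stressor]
        if sc.n_planted_dmps == 0:
            continue
        n_hyper = int(round(sc.n_planted_dmps * sc.hyper_fraction))
        n_hypo = sc.n_planted_dmps - n_hyper
        hypo_pool = np.flatnonzero(meth_mask & ~taken)
        n_from_pool = min(n_hypo, len(hypo_pool))
        hypo_idx = (rng.choice(hypo_pool, size=n_from_pool, replace=False)
                    if n_from_pool else np.array([], dtype=int))
        n_convert = n_hypo - n_from_pool
        if n_convert > 0:
            free = np.flatnonzero(~meth_mask & ~taken)
            if len(free) < n_convert:
                raise ValueError(f"{stressor}: not enough sites to plant "
                                 f"{n_hypo} hypomethylated DMPs")
            w = genic_weights[free]
            conv = rng.choice(free, size=n_convert, replace=False, p=w / w.sum())
            p_site[conv] = rng.beta(a_hi, b_hi, size=n_convert)
            meth_mask[conv] = True
            hypo_idx = np.concatenate([hypo_idx, conv])
        taken[hypo_idx] = True
        hyper_pool = np.flatnonzero(~taken)
        hyper_idx = rng.choice(hyper_pool, size=n_hyper, replace=False)
        taken[hyper_idx] = True
        for idx_arr, direction in ((hyper_idx, "hyper"), (hypo_idx, "hypo")):
            for i in np.sort(idx_arr):
                if rng.random() < sc.persistence_prob:
                    pclass = "transgenerational"
                else:
                    names = list(_NONPERSISTENT_WEIGHTS)
                    w = np.array([_NONPERSISTENT_WEIGHTS[n] for n in names])
                    pclass = names[rng.choice(len(names), p=w / w.sum())]
                delta = sc.effect_size / 100.0 * (1 if direction == "hyper" else -1)
                clamped = not (0.0 <= p_site[i] + delta <= 1.0)
                rows.append({
                    "chrom": sites["chrom"].iat[i], "pos": int(sites["pos"].iat[i]),
                    "site_index": int(i), "treatment": stressor,
                    "direction": direction, "effect_size": sc.effect_size,
                    "persistence_class": pclass, "clamped": clamped,
                })
    return pd.DataFrame(rows, columns=["chrom", "pos", "site_index", "treatment",
                                       "direction", "effect_size",
                                       "persistence_class", "clamped"])


def _class_active(pclass: str, generation: str) -> bool:
    if generation == "F1":
        return True
    if generation == "F2":
        return pclass in ("F1F2", "transgenerational")
    if generation == "F4":
        return pclass in ("F1F4", "transgenerational")
    return False


def truth_active_sites(truth: pd.DataFrame, treatment: str,
                       generation: str) -> set[tuple[str, int]]:
    """Site keys of planted DMPs active for a treatment in a generation."""
    if truth.empty:
        return set()
    sub = truth[truth["treatment"] == treatment]
    active = sub[[_class_active(c, generation) for c in sub["persistence_class"]]]
    return set(zip(active["chrom"], active["pos"]))


def transgenerational_truth(truth: pd.DataFrame,
                            treatment: str) -> set[tuple[str, int]]:
    if truth.empty:
        return set()
    sub = truth[(truth["treatment"] == treatment)
                & (truth["persistence_class"] == "transgenerational")]
    return set(zip(sub["chrom"], sub["pos"]))


def simulate_experiment(config: SimulationConfig,
                        annotation: GenomeAnnotation
                        ) -> tuple[MethylationMatrix, SampleSheet, pd.DataFrame]:
    """Generate the full count matrix, sample sheet and planted-DMP truth table."""
    config.validate()
    sites = simulate_cpg_sites(config)
    n = len(sites)

    # site-level baseline methylation: two-component mixture with genic bias
    rng_levels = stage_rng(config.master_seed, "site_levels", extra=1)
    feats = classify_sites(sites, annotation)
    w = np.ones(n)
    w[feats != "intergenic"] *= config.genebody_enrichment
    w[feats == "exon"] *= config.exon_enrichment
    n_meth = int(round(config.baseline_methylated_fraction * n))
    meth_mask = np.zeros(n, dtype=bool)
    if n_meth > 0:
        meth_idx = rng_levels.choice(n, size=n_meth, replace=False, p=w / w.sum())
        meth_mask[meth_idx] = True
    a_lo, b_lo = config.low_meth_beta_params
    a_hi, b_hi = config.high_meth_beta_params
    p_site = rng_levels.beta(a_lo, b_lo, size=n)
    p_site[meth_mask] = rng_levels.beta(a_hi, b_hi, size=int(meth_mask.sum()))

    truth = _plant_dmps(config, sites, p_site, meth_mask, genic_weights=w)
    sheet = _build_sample_sheet(config)
    samples = sheet.frame

    # per-sample site means
    p_mean = np.repeat(p_site[:, None], len(samples), axis=1)
    for j, row in enumerate(samples.itertuples(index=False)):
        if row.treatment == "azacytidine":
            factor = (config.aza_f1_factor if row.generation == "F1"
                      else config.aza_recovery_factor)
            p_mean[:, j] *= factor
        if row.treatment != "control" and not truth.empty:
            sub = truth[truth["treatment"] == row.treatment]
            for t in sub.itertuples(index=False):
                if _class_active(t.persistence_class, row.generation):
                    delta = t.effect_size / 100.0 * (1 if t.direction == "hyper" else -1)
                    p_mean[t.site_index, j] = min(1.0, max(
                        0.0, p_mean[t.site_index, j] + delta))

    # coverage: shared site mappability factor x library factor, Poisson counts
    rng_cov = stage_rng(config.master_seed, "coverage")
    w_map = config.mappable_fraction
    mu1 = config.mappable_coverage_factor
    mu2 = (1.0 - w_map * mu1) / (1.0 - w_map) if w_map < 1 else 1.0
    is_mappable = rng_cov.random(n) < w_map
    g_site = np.where(
        is_mappable,
        rng_cov.gamma(config.mappable_shape, mu1 / config.mappable_shape, n),
        rng_cov.gamma(config.coverage_dispersion,
                      mu2 / config.coverage_dispersion, n))
    lo, hi = config.library_factor_range
    l_lib = rng_cov.uniform(lo, hi, size=len(samples))
    total = rng_cov.poisson(config.coverage_mean * np.outer(g_site, l_lib))

    # beta-binomial methylated counts
    rng_counts = stage_rng(config.master_seed, "counts")
    phi = config.sample_dispersion
    p_cell = p_mean
    if phi > 0:
        interior = (p_mean > 0) & (p_mean < 1)
        a = np.where(interior, p_mean * (1 - phi) / phi, 1.0)
        b = np.where(interior, (1 - p_mean) * (1 - phi) / phi, 1.0)
        draws = rng_counts.beta(a, b)
        p_cell = np.where(interior, draws, p_mean)
    meth = rng_counts.binomial(total, p_cell)

    matrix = MethylationMatrix(sites, samples["sample_id"].tolist(),
                               meth.astype(np.int64), total.astype(np.int64))
    return matrix, sheet, truth


def simulate_lifehistory(config: SimulationConfig) -> pd.DataFrame:
    """Per-individual brood ages/sizes with treatment x generation effects.

    Stressor treatments reduce brood sizes in early generations (strongest in
    F0/F1, recovering by F4); clone lines carry a lognormal random brood
    multiplier.  Individuals with both broods zero are flagged unreproductive.
    """
    config.validate()
    rng = stage_rng(config.master_seed, "lifehistory")
    treatments = ["control"] + sorted(config.stressors)
    generations = ["F0", "F1", "F2", "F3", "F4"]
    clones = [f"B{i + 1}" for i in range(config.lh_n_clones)]
    clone_mult = {c: float(np.exp(rng.normal(0.0, config.lh_clone_sd)))
                  for c in clones}
    rows = []
    ind = 0
    for treatment in treatments:
        exps = (sorted(set(TREATMENT_EXPERIMENT.values()))
                if treatment == "control" else [TREATMENT_EXPERIMENT[treatment]])
        for exp in exps:
            for gen in generations:
                effect = (1.0 if treatment == "control"
                          else config.lh_stressor_brood_effect.get(gen, 1.0))
                for k in range(config.lh_individuals_per_cell):
                    ind += 1
                    clone = clones[k % len(clones)]
                    m = effect * clone_mult[clone]
                    age1 = max(1.0, rng.normal(config.lh_age1_mean, config.lh_age1_sd))
                    age2 = age1 + max(0.5, rng.normal(config.lh_interbrood_mean,
                                                      config.lh_interbrood_sd))
                    brood1 = int(rng.poisson(config.lh_brood1_mean * m))
                    brood2 = int(rng.poisson(config.lh_brood2_mean * m))
                    rows.append({
                        "individual_id": f"ind{ind:05d}", "experiment": exp,
                        "treatment": treatment, "generation": gen,
                        "clone_line": clone,
                        "age_first_repro": round(age1, 2),
                        "brood1_size": brood1,
                        "age_second_repro": round(age2, 2),
                        "brood2_size": brood2,
                        "unreproductive": brood1 == 0 and brood2 == 0,
                    })
    return pd.DataFrame(rows)
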