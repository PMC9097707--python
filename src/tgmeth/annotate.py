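"""Positional annotation of CpG sites and GO-term enrichment.

Feature classification is a partition: every site is exactly one of exon,
intron (inside a gene but outside all of its exons) or intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenomeAnnotation, SiteKey
from .stats_util import adjust_bh

FEATURES = ("exon", "intron", "intergenic")


def _merged_intervals(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge 1-based inclusive intervals; return sorted (starts, ends)."""
    if not intervals:
        return np.array([], dtype=int), np.array([], dtype=int)
    ivs = sorted(intervals)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts), np.array(ends)


def _contained(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorised containment in sorted non-overlapping inclusive intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] <= ends[i[ok]]
    return out


def classify_sites(sites: pd.DataFrame, ann: GenomeAnnotation) -> np.ndarray:
    """Classify each (chrom, pos) site as exon / intron / intergenic."""
    result = np.full(len(sites), "intergenic", dtype=object)
    by_chrom = ann.genes_by_chrom()
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        genes = by_chrom.get(chrom, [])
        if not genes:
            continue
        pos = sites["pos"].to_numpy()[idx]
        gs, ge = _merged_intervals([(g.start, g.end) for g in genes])
        xs, xe = _merged_intervals([iv for g in genes for iv in g.exons])
        in_gene = _contained(pos, gs, ge)
        in_exon = _contained(pos, xs, xe) & in_gene
        result[idx[in_exon]] = "exon"
        result[idx[in_gene & ~in_exon]] = "intron"
    return result


def assign_nearest_gene(sites: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Assign each site to its nearest gene.

    Distance is 0 inside a gene; otherwise the distance to the nearest gene
    boundary.  Ties break by smaller distance, then leftmost gene start, then
    lexicographic gene_id.  Sites on chromosomes absent from the annotation
    get gene_id None and NaN distance (flagged intergenic).
    """
    by_chrom = ann.genes_by_chrom()
    gene_ids = np.empty(len(sites), dtype=object)
    distances = np.full(len(sites), np.nan)
    features = np.full(len(sites), "intergenic", dtype=object)

    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        genes = by_chrom.get(chrom, [])
        if not genes:
            gene_ids[idx] = None
            continue
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        names = np.array([g.gene_id for g in genes], dtype=object)
        order = np.lexsort((names, starts))  # pre-ranked tie-break order
        exon_iv = [
            _merged_intervals(g.exons) for g in genes
        ]
        pos_arr = sites["pos"].to_numpy()[idx]
        for k, p in enumerate(pos_arr):
            d = np.maximum(0, np.maximum(starts - p, p - ends))
            best = min(order, key=lambda j: (d[j], starts[j], names[j]))
            g = genes[best]
            gene_ids[idx[k]] = g.gene_id
            distances[idx[k]] = d[best]
            if d[best] == 0:
                xs, xe = exon_iv[best]
                inside_exon = bool(_contained(np.array([p]), xs, xe)[0])
                features[idx[k]] = "exon" if inside_exon else "intron"
    out = sites[["chrom", "pos"]].copy().reset_index(drop=True)
    out["gene_id"] = gene_ids
    out["distance"] = distances
    out["feature"] = features
    return out


def genomic_distribution(dmp_sites: pd.DataFrame, all_sites: pd.DataFrame,
                         ann: GenomeAnnotation) -> dict:
    """Gene-body / exon / intron proportions for a DMP list vs the genome-wide
    CpG background (strict containment)."""

    def summarise(sites: pd.DataFrame) -> dict:
        feats = classify_sites(sites, ann)
        n = len(sites)
        n_exon = int(np.sum(feats == "exon"))
        n_intron = int(np.sum(feats == "intron"))
        n_genic = n_exon + n_intron
        return {
            "n": n,
            "genebody_pct": 100.0 * n_genic / n if n else float("nan"),
            "exon_share_of_genebody_pct":
                100.0 * n_exon / n_genic if n_genic else float("nan"),
            "intron_share_of_genebody_pct":
                100.0 * n_intron / n_genic if n_genic else float("nan"),
        }

    return {"dmp": summarise(dmp_sites), "background": summarise(all_sites)}


def gene_dmp_clustering(assignments: pd.DataFrame) -> dict:
    """Within-gene DMP clustering summary.

    Uses only in-gene assignments (distance 0).  Pairwise distances are
    |position difference| between consecutive position-sorted DMPs in the
    same gene; the median is over all such consecutive pairs.
    """
    genic = assignments[(assignments["distance"] == 0)
                        & assignments["gene_id"].notna()]
    counts = genic.groupby("gene_id")["pos"].count()
    distances: list[int] = []
    for _, grp in genic.groupby("gene_id"):
        ps = np.sort(grp["pos"].to_numpy())
        distances.extend(np.diff(ps).tolist())
    n_genes = int(len(counts))
    n_multi = int((counts >= 2).sum())
    return {
        "genes_with_dmp": n_genes,
        "genes_with_multiple_dmps": n_multi,
        "fraction_multi_pct": 100.0 * n_multi / n_genes if n_genes else float("nan"),
        "median_pairwise_distance_bp":
            float(np.median(distances)) if distances else float("nan"),
        "per_gene_counts": counts.to_dict(),
    }


def go_enrichment(study_genes: set[str], background_genes: set[str],
                  go_map: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of GO terms in the study gene set.

    The 2x2 table per term is (study-with-term, study-without-term,
    background-only-with-term, background-only-without-term); BH adjustment
    across terms.  Terms with no background gene are skipped.
    """
    if not study_genes <= background_genes:
        raise ValueError("study genes must be a subset of the background")
    terms: dict[str, set[str]] = {}
    for gene in background_genes:
        for t in go_map.get(gene, ()):
            terms.setdefault(t, set()).add(gene)

    rows = []
    n_study = len(study_genes)
    n_bg_only = len(background_genes) - n_study
    for term in sorted(terms):
        genes_t = terms[term]
        a = len(genes_t & study_genes)
        b = n_study - a
        c = len(genes_t) - a
        d = n_bg_only - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term": term, "study_count": a, "background_count": len(genes_t),
                     "p_value": float(p)})
    df = pd.DataFrame(rows, columns=["term", "study_count", "background_count",
                                     "p_value"])
    if len(df):
        df["q_value"] = adjust_bh(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q_value"] = []
    return df
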