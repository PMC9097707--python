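"""Transgenerational DMP calling: generation intersections and characterisation.

A transgenerational DMP is a site significant in all three generations (F1,
F2 and F4) of a treatment's comparisons.  Sign consistency is reported, not
enforced, in this primary strategy; the alternative two-stage strategy
(lenient F1 screen, per-generation confirmation) enforces it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dm import ComparisonDesign, DMPSet, adjust_bh, call_dmps, test_generation
from .matrix import MethylationMatrix, SiteKey


@dataclass
class VennPartition:
    """The seven disjoint regions of the F1/F2/F4 three-set Venn diagram."""

    f1_only: set[SiteKey]
    f2_only: set[SiteKey]
    f4_only: set[SiteKey]
    f1f2: set[SiteKey]
    f1f4: set[SiteKey]
    f2f4: set[SiteKey]
    center: set[SiteKey]

    @property
    def f1_total(self) -> int:
        return len(self.f1_only) + len(self.f1f2) + len(self.f1f4) + len(self.center)

    @property
    def f2_total(self) -> int:
        return len(self.f2_only) + len(self.f1f2) + len(self.f2f4) + len(self.center)

    @property
    def f4_total(self) -> int:
        return len(self.f4_only) + len(self.f1f4) + len(self.f2f4) + len(self.center)

    def region_counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name))
                for name in ("f1_only", "f2_only", "f4_only",
                             "f1f2", "f1f4", "f2f4", "center")}

    @property
    def union_size(self) -> int:
        return sum(self.region_counts().values())


def intersect_generations(dmps_f1: DMPSet, dmps_f2: DMPSet,
                          dmps_f4: DMPSet) -> VennPartition:
    """Exact set algebra on site keys; no effect-size threshold applied."""
    a, b, c = dmps_f1.keys(), dmps_f2.keys(), dmps_f4.keys()
    return VennPartition(
        f1_only=a - b - c,
        f2_only=b - a - c,
        f4_only=c - a - b,
        f1f2=(a & b) - c,
        f1f4=(a & c) - b,
        f2f4=(b & c) - a,
        center=a & b & c,
    )


def persistence_fraction(partition: VennPartition,
                         relative_to: str = "F1") -> float:
    """Percent of the reference generation's DMPs in the triple intersection,
    reported to one decimal place."""
    totals = {"F1": partition.f1_total, "F2": partition.f2_total,
              "F4": partition.f4_total}
    denom = totals[relative_to]
    if denom == 0:
        raise ValueError(f"{relative_to} DMP set is empty")
    return round(100.0 * len(partition.center) / denom, 1)


def check_sign_consistency(partition: VennPartition,
                           results_by_gen: dict[str, pd.DataFrame]
                           ) -> pd.DataFrame:
    """Per-center-site hypo/hyper direction in each generation + flag."""
    lookups = {}
    for gen, res in results_by_gen.items():
        lookups[gen] = {(c, int(p)): d for c, p, d in
                        zip(res["chrom"], res["pos"], res["meth_diff"])}
    rows = []
    for key in sorted(partition.center):
        dirs = {}
        for gen in ("F1", "F2", "F4"):
            diff = lookups[gen].get(key)
            if diff is None:
                raise ValueError(f"center site {key} missing from {gen} results")
            dirs[gen] = "hyper" if diff > 0 else ("hypo" if diff < 0 else "zero")
        rows.append({"chrom": key[0], "pos": key[1],
                     "dir_F1": dirs["F1"], "dir_F2": dirs["F2"],
                     "dir_F4": dirs["F4"],
                     "consistent": len(set(dirs.values())) == 1})
    df = pd.DataFrame(rows, columns=["chrom", "pos", "dir_F1", "dir_F2",
                                     "dir_F4", "consistent"])
    df.attrs["fraction_consistent"] = (float(df["consistent"].mean())
                                       if len(df) else float("nan"))
    return df


def effect_size_pairs(result_f1: pd.DataFrame, result_f4: pd.DataFrame,
                      center: set[SiteKey]) -> pd.DataFrame:
    """Paired (F1, F4) methylation differences for the transgenerational set."""
    def lookup(res):
        return {(c, int(p)): d for c, p, d in
                zip(res["chrom"], res["pos"], res["meth_diff"])}

    l1, l4 = lookup(result_f1), lookup(result_f4)
    rows = [{"chrom": k[0], "pos": k[1],
             "meth_diff_F1": l1[k], "meth_diff_F4": l4[k]}
            for k in sorted(center) if k in l1 and k in l4]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_diff_F1",
                                     "meth_diff_F4"])
    if len(df) >= 2 and df["meth_diff_F1"].std() > 0 and df["meth_diff_F4"].std() > 0:
        r = float(np.corrcoef(df["meth_diff_F1"], df["meth_diff_F4"])[0, 1])
        slope = float(np.polyfit(df["meth_diff_F1"], df["meth_diff_F4"], 1)[0])
    else:
        r, slope = float("nan"), float("nan")
    df.attrs["correlation"] = r
    df.attrs["slope"] = slope
    return df


def alternative_two_stage(prepared: MethylationMatrix, design: ComparisonDesign,
                          fdr1: float = 0.20, p2: float = 0.05,
                          d0: float = 20.0, method: str = "wald") -> DMPSet:
    """Two-stage transgenerational calling on the filtered comparison matrix.

    Stage 1 screens F1 cases against F1 controls only (3 vs 3) at a lenient
    BH FDR; stage 2 retests the candidates 3-vs-3 within F2 and within F4 and
    keeps those with unadjusted p <= p2 in both and the same sign as in F1.
    """
    f1_res = test_generation(prepared, design.case_samples["F1"],
                             design.control_samples["F1"], d0=d0, method=method)
    cand = f1_res[(f1_res["q_value"] <= fdr1) & (f1_res["meth_diff"] != 0)]
    if cand.empty:
        return DMPSet(sites={}, label=f"{design.treatment}:two-stage")
    sign_f1 = {(c, int(p)): np.sign(d) for c, p, d in
               zip(cand["chrom"], cand["pos"], cand["meth_diff"])}

    keep = set(sign_f1)
    for gen in ("F2", "F4"):
        res = test_generation(prepared, design.case_samples[gen],
                              design.control_samples[gen], d0=d0, method=method)
        ok = {}
        for c, p, d, pv in zip(res["chrom"], res["pos"], res["meth_diff"],
                               res["p_value"]):
            key = (c, int(p))
            if key in keep and pv <= p2 and np.sign(d) == sign_f1[key]:
                ok[key] = True
        keep &= set(ok)
    sites = {k: ("hyper" if sign_f1[k] > 0 else "hypo") for k in keep}
    return DMPSet(sites=sites, label=f"{design.treatment}:two-stage")


def strategy_concordance(primary: DMPSet, alternative: DMPSet) -> float:
    """Percent of the primary call set also found by the alternative strategy."""
    if len(primary) == 0:
        return 0.0
    return 100.0 * len(primary.keys() & alternative.keys()) / len(primary)


def cross_stressor_overlap(sets: dict[str, DMPSet]) -> dict:
    """Pairwise and higher-order intersection sizes across stressor sets."""
    if len(sets) < 2:
        raise ValueError("need at least two stressor sets")
    names = sorted(sets)
    out: dict = {"pairwise": {}, "higher_order": {}}
    for a, b in itertools.combinations(names, 2):
        out["pairwise"][f"{a}&{b}"] = len(sets[a].keys() & sets[b].keys())
    for k in range(3, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inter = set.intersection(*(sets[c].keys() for c in combo))
            out["higher_order"]["&".join(combo)] = len(inter)
    return out
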