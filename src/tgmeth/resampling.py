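"""Permutation machinery: label-shuffling nulls and CpG-set overlap tests.

Two distinct permutation machines:

* whole-analysis label shuffling: the (case/control, generation) labels of
  the 18 samples of one comparison are randomly reassigned (preserving the
  3-per-cell design shape) and the full per-generation 3-vs-9 analysis plus
  the transgenerational intersection is rerun;
* overlap resampling: the significance of a k-way DMP-set intersection is
  assessed by drawing same-size random CpG sets from the universe of tested
  sites.

Permutation p-values use the add-one rule p = (1 + #{null >= obs}) / (1 + B),
so they are never exactly zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dm import ComparisonDesign, DMPSet, call_dmps, test_generation
from .matrix import MethylationMatrix, SiteKey
from .transgen import intersect_generations

log = logging.getLogger(__name__)

_GENS = ("F1", "F2", "F4")


def permute_labels(design: ComparisonDesign,
                   rng: np.random.Generator) -> ComparisonDesign:
    """Uniformly reassign (case/control, generation) labels over the samples.

    Group sizes are preserved: each of the six (role, generation) cells keeps
    its original size, so every permuted analysis is well defined.
    """
    cells: list[tuple[str, str, int]] = []
    samples: list[str] = []
    for gen in _GENS:
        if gen in design.case_samples:
            cells.append(("case", gen, len(design.case_samples[gen])))
            samples.extend(design.case_samples[gen])
    for gen in _GENS:
        if gen in design.control_samples:
            cells.append(("control", gen, len(design.control_samples[gen])))
            samples.extend(design.control_samples[gen])
    perm = rng.permutation(len(samples))
    shuffled = [samples[i] for i in perm]
    case: dict[str, list[str]] = {}
    ctrl: dict[str, list[str]] = {}
    cursor = 0
    for role, gen, size in cells:
        chunk = shuffled[cursor:cursor + size]
        cursor += size
        (case if role == "case" else ctrl)[gen] = chunk
    return ComparisonDesign(treatment=f"{design.treatment}:permuted",
                            experiment=design.experiment,
                            case_samples=case, control_samples=ctrl)


def permutation_null_run(prepared: MethylationMatrix, design: ComparisonDesign,
                         n_perm: int = 100,
                         rng: np.random.Generator | None = None,
                         fdr: float = 0.05, d0: float = 20.0,
                         method: str = "wald") -> dict:
    """Rerun the full per-generation analysis under shuffled sample labels.

    ``prepared`` must already be the filtered/normalised comparison matrix
    (the filters depend only on the sample set, which permutation preserves).
    Returns the observed run's p-values and transgenerational count together
    with, per permutation, the pooled null p-values and the number of
    transgenerational DMPs.  A failed permutation is recorded, not fatal.
    """
    if rng is None:
        rng = np.random.default_rng()

    def analyse(d: ComparisonDesign) -> tuple[np.ndarray, int]:
        results, dmps = {}, {}
        for gen in _GENS:
            res = test_generation(prepared, d.case_samples[gen],
                                  d.control_pool, d0=d0, method=method)
            results[gen] = res
            dmps[gen] = call_dmps(res, fdr=fdr)
        part = intersect_generations(dmps["F1"], dmps["F2"], dmps["F4"])
        pooled = np.concatenate([results[g]["p_value"].to_numpy() for g in _GENS])
        return pooled, len(part.center)

    obs_p, obs_count = analyse(design)
    null_p: list[np.ndarray] = []
    null_counts: list[int] = []
    failures = 0
    for b in range(n_perm):
        try:
            pd_, count = analyse(permute_labels(design, rng))
            null_p.append(pd_)
            null_counts.append(count)
        except Exception:  # noqa: BLE001 - a failed permutation is recorded
            failures += 1
            log.warning("permutation %d failed; recorded and skipped", b)
    return {
        "observed_p_values": obs_p,
        "observed_transgenerational": obs_count,
        "null_p_values": null_p,
        "null_transgenerational_counts": null_counts,
        "total_null_transgenerational": int(np.sum(null_counts)),
        "n_permutations": n_perm,
        "n_failed": failures,
    }


def _as_index_sets(observed_sets: list[set[SiteKey]],
                   universe: list[SiteKey]) -> tuple[list[np.ndarray], int]:
    index = {k: i for i, k in enumerate(universe)}
    out = []
    for s in observed_sets:
        if not set(s) <= set(index):
            raise ValueError("observed set contains sites outside the universe")
        out.append(np.fromiter((index[k] for k in s), dtype=int, count=len(s)))
    return out, len(universe)


def overlap_permutation_test(observed_sets: list[set[SiteKey]],
                             universe: list[SiteKey], n_perm: int = 1000,
                             rng: np.random.Generator | None = None) -> dict:
    """Significance of the k-way intersection by random same-size resampling.

    Null draws are independent uniform samples without replacement from the
    tested-site universe, one per observed set; the statistic is the size of
    the k-way intersection; add-one p-value.
    """
    if rng is None:
        rng = np.random.default_rng()
    idx_sets, n_universe = _as_index_sets(observed_sets, universe)
    sizes = [len(s) for s in idx_sets]
    if any(s > n_universe for s in sizes):
        raise ValueError("observed set larger than the universe")

    observed = len(set.intersection(*(set(s.tolist()) for s in idx_sets))) \
        if idx_sets else 0
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        mask = np.ones(n_universe, dtype=np.uint8)
        count = n_universe
        for size in sizes:
            draw = rng.choice(n_universe, size=size, replace=False)
            m = np.zeros(n_universe, dtype=np.uint8)
            m[draw] = 1
            mask &= m
        null[b] = int(mask.sum())
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return {
        "observed": observed,
        "p_value": p,
        "null_mean": float(null.mean()) if n_perm else float("nan"),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else float("nan"),
        "n_perm": n_perm,
    }


def cross_stressor_overlap_test(transgen_sets: dict[str, DMPSet],
                                universe: list[SiteKey], n_perm: int = 1000,
                                rng: np.random.Generator | None = None
                                ) -> dict[str, dict]:
    """Pairwise overlap permutation tests between stressors' call sets."""
    if rng is None:
        rng = np.random.default_rng()
    names = sorted(transgen_sets)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}&{b}"] = overlap_permutation_test(
                [transgen_sets[a].keys(), transgen_sets[b].keys()],
                universe, n_perm=n_perm, rng=rng)
    return out
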