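"""Set algebra of generation intersections and derived summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tgmeth.dm import DMPSet
from tgmeth.transgen import (VennPartition, cross_stressor_overlap,
                             effect_size_pairs, intersect_generations,
                             persistence_fraction, strategy_concordance,
                             check_sign_consistency)


def dmpset(keys, direction="hyper"):
    return DMPSet(sites={k: direction for k in keys})


def key(i):
    return ("chr1", i)


class TestVenn:
    def test_identical_sets(self):
        s = dmpset([key(i) for i in range(5)])
        part = intersect_generations(s, s, s)
        assert len(part.center) == 5
        assert part.union_size == 5
        counts = part.region_counts()
        assert all(v == 0 for r, v in counts.items() if r != "center")

    def test_disjoint_sets(self):
        a = dmpset([key(1)])
        b = dmpset([key(2)])
        c = dmpset([key(3)])
        part = intersect_generations(a, b, c)
        assert len(part.center) == 0
        assert part.union_size == 3

    def test_regions_match_bitmask_oracle(self):
        rng = np.random.default_rng(0)
        universe = [key(i) for i in range(40)]
        sets = [set(rng.choice(40, size=15, replace=False)) for _ in range(3)]
        a, b, c = [dmpset([key(i) for i in s]) for s in sets]
        part = intersect_generations(a, b, c)
        # bitmask oracle: membership pattern of each site
        regions = {m: 0 for m in range(1, 8)}
        for i in range(40):
            m = (i in sets[0]) | ((i in sets[1]) << 1) | ((i in sets[2]) << 2)
            if m:
                regions[m] += 1
        counts = part.region_counts()
        assert counts["f1_only"] == regions[0b001]
        assert counts["f2_only"] == regions[0b010]
        assert counts["f4_only"] == regions[0b100]
        assert counts["f1f2"] == regions[0b011]
        assert counts["f1f4"] == regions[0b101]
        assert counts["f2f4"] == regions[0b110]
        assert counts["center"] == regions[0b111]
        assert part.union_size == sum(regions.values())

    def test_permutation_invariance_of_center(self):
        rng = np.random.default_rng(1)
        sets = [dmpset([key(int(i)) for i in rng.choice(30, 12, replace=False)])
                for _ in range(3)]
        centers = {frozenset(intersect_generations(*perm).center)
                   for perm in itertools.permutations(sets)}
        assert len(centers) == 1


class TestPersistence:
    def test_reported_fraction_microcystin_style(self):
        # 130 of 225 F1 DMPs persist -> 57.8%
        part = VennPartition(
            f1_only={key(i) for i in range(95)}, f2_only=set(), f4_only=set(),
            f1f2=set(), f1f4=set(), f2f4=set(),
            center={key(1000 + i) for i in range(130)})
        assert part.f1_total == 225
        assert persistence_fraction(part) == 57.8

    def test_reported_fraction_demethylation_style(self):
        # 26 of 2231 -> 1.2% at one decimal
        part = VennPartition(
            f1_only={key(i) for i in range(2205)}, f2_only=set(),
            f4_only=set(), f1f2=set(), f1f4=set(), f2f4=set(),
            center={key(10_000 + i) for i in range(26)})
        assert persistence_fraction(part) == 1.2

    def test_full_persistence(self):
        part = VennPartition(set(), set(), set(), set(), set(), set(),
                             center={key(i) for i in range(7)})
        assert persistence_fraction(part) == 100.0

    def test_scale_free_under_duplication(self):
        a = {key(i) for i in range(20)}
        c = {key(i) for i in range(8)}
        part = VennPartition(a - c, set(), set(), set(), set(), set(), c)
        base = persistence_fraction(part)
        a2 = a | {("chr2", i) for i in range(20)}
        c2 = c | {("chr2", i) for i in range(8)}
        part2 = VennPartition(a2 - c2, set(), set(), set(), set(), set(), c2)
        assert persistence_fraction(part2) == base

    def test_empty_reference_raises(self):
        part = VennPartition(set(), set(), set(), set(), set(), set(), set())
        with pytest.raises(ValueError):
            persistence_fraction(part)


class TestSignConsistency:
    def _results(self, diffs):
        return {gen: pd.DataFrame({"chrom": ["chr1"], "pos": [1],
                                   "meth_diff": [d]})
                for gen, d in diffs.items()}

    def test_consistent_site(self):
        part = VennPartition(set(), set(), set(), set(), set(), set(),
                             {key(1)})
        tab = check_sign_consistency(part, self._results(
            {"F1": 20.0, "F2": 15.0, "F4": 30.0}))
        assert tab["consistent"].all()
        assert tab.attrs["fraction_consistent"] == 1.0

    def test_flipped_site_flagged(self):
        part = VennPartition(set(), set(), set(), set(), set(), set(),
                             {key(1)})
        tab = check_sign_consistency(part, self._results(
            {"F1": 20.0, "F2": -15.0, "F4": 30.0}))
        assert not tab["consistent"].iloc[0]


class TestEffectPairs:
    def test_identical_results_on_identity_line(self):
        res = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [1, 2, 3, 4],
                            "meth_diff": [10.0, -20.0, 35.0, 5.0]})
        pairs = effect_size_pairs(res, res, {key(i) for i in (1, 2, 3, 4)})
        assert (pairs["meth_diff_F1"] == pairs["meth_diff_F4"]).all()
        assert pairs.attrs["correlation"] == pytest.approx(1.0)

    def test_empty_center(self):
        res = pd.DataFrame({"chrom": [], "pos": [], "meth_diff": []})
        pairs = effect_size_pairs(res, res, set())
        assert pairs.empty


class TestConcordance:
    def test_equal_sets(self):
        s = dmpset([key(i) for i in range(4)])
        assert strategy_concordance(s, s) == 100.0

    def test_disjoint_sets(self):
        assert strategy_concordance(dmpset([key(1)]), dmpset([key(2)])) == 0.0

    def test_partial_overlap_arithmetic(self):
        primary = dmpset([key(i) for i in range(4)])
        alt = dmpset([key(i) for i in (0, 1, 2, 9)])
        assert strategy_concordance(primary, alt) == 75.0

    def test_empty_primary_flagged_zero(self):
        assert strategy_concordance(dmpset([]), dmpset([key(1)])) == 0.0


class TestCrossStressor:
    def test_disjoint(self):
        sets = {"a": dmpset([key(1)]), "b": dmpset([key(2)]),
                "c": dmpset([key(3)])}
        out = cross_stressor_overlap(sets)
        assert all(v == 0 for v in out["pairwise"].values())
        assert out["higher_order"]["a&b&c"] == 0

    def test_identical_pair(self):
        s = dmpset([key(i) for i in range(6)])
        out = cross_stressor_overlap({"a": s, "b": s})
        assert out["pairwise"]["a&b"] == 6

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        raw = {n: set(map(int, rng.choice(25, 10, replace=False)))
               for n in "abcd"}
        sets = {n: dmpset([key(i) for i in s]) for n, s in raw.items()}
        out = cross_stressor_overlap(sets)
        for pair, size in out["pairwise"].items():
            x, y = pair.split("&")
            assert size == len(raw[x] & raw[y])
        for combo, size in out["higher_order"].items():
            names = combo.split("&")
            assert size == len(set.intersection(*(raw[n] for n in names)))
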