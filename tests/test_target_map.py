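import itertools
import math

import numpy as np
import pytest

from enhancerstate.core_io import GeneModel, GenomicInterval, InteractionPair
from enhancerstate.target_map import (
    TargetAssignment,
    chiapet_targets,
    expression_change_test,
    gained_interaction_targets,
    lineage_activation_fraction,
    nearest_gene_targets,
)
from enhancerstate.transcription_quant import ExpressionTable


def _expr(values):
    return ExpressionTable(values=dict(values))


class TestNearestGeneTargets:
    GENES = [
        GeneModel("gA", "chr1", "+", 1_000, 5_000),
        GeneModel("gB", "chr1", "+", 20_000, 25_000),
    ]

    def test_nearer_gene_wins(self):
        region = GenomicInterval("chr1", 4_000, 4_200, name="r1")
        out = nearest_gene_targets([region], self.GENES)
        assert out.targets == {"r1": {"gA"}}
        assert out.method == "nearest"

    def test_equidistant_tie_takes_smaller_gene_id(self):
        region = GenomicInterval("chr1", 10_400, 10_600, name="r1")  # 9,500 both
        out = nearest_gene_targets([region], self.GENES)
        assert out.targets["r1"] == {"gA"}

    def test_matches_exhaustive_oracle(self, rng):
        genes = [
            GeneModel(f"g{i:02d}", "chr1", "+", int(t), int(t) + 500)
            for i, t in enumerate(rng.integers(0, 500_000, size=40))
        ]
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 200, name=f"r{i}")
            for i, s in enumerate(rng.integers(0, 500_000, size=500))
        ]
        out = nearest_gene_targets(regions, genes)
        for r in regions:
            oracle = min((abs(r.center - g.tss), g.gene_id) for g in genes)[1]
            assert out.targets[r.name] == {oracle}


def _chiapet_bruteforce(regions, interactions, genes, hw):
    targets = {r.name: set() for r in regions}
    for r in regions:
        for pair in interactions:
            for a, b in ((pair.anchor1, pair.anchor2),
                         (pair.anchor2, pair.anchor1)):
                if not (a.chrom == r.chrom and a.start < r.end and r.start < a.end):
                    continue
                for g in genes:
                    lo, hi = max(0, g.tss - hw), g.tss + hw
                    if b.chrom == g.chrom and b.start < hi and lo < b.end:
                        targets[r.name].add(g.gene_id)
    return targets


class TestChiapetTargets:
    def test_single_interaction_links_region_to_promoter(self):
        region = GenomicInterval("chr1", 100_000, 100_200, name="r1")
        gene = GeneModel("gA", "chr1", "+", 300_000, 310_000)
        pair = InteractionPair(
            GenomicInterval("chr1", 99_950, 100_150),
            GenomicInterval("chr1", 298_000, 298_500),
        )
        out = chiapet_targets([region], [pair], [gene])
        assert out.targets == {"r1": {"gA"}}

    def test_anchor_missing_all_promoters_gives_no_target(self):
        region = GenomicInterval("chr1", 100_000, 100_200, name="r1")
        gene = GeneModel("gA", "chr1", "+", 300_000, 310_000)
        pair = InteractionPair(
            GenomicInterval("chr1", 99_950, 100_150),
            GenomicInterval("chr1", 500_000, 500_500),
        )
        out = chiapet_targets([region], [pair], [gene])
        assert out.targets == {"r1": set()}

    def test_matches_triple_loop_oracle(self, rng):
        genes = [
            GeneModel(f"g{i:02d}", "chr1", "+", int(t), int(t) + 500)
            for i, t in enumerate(rng.integers(0, 800_000, size=30))
        ]
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 300, name=f"r{i:03d}")
            for i, s in enumerate(rng.integers(0, 800_000, size=200))
        ]
        interactions = [
            InteractionPair(
                GenomicInterval("chr1", int(a), int(a) + 400),
                GenomicInterval("chr1", int(b), int(b) + 400),
            )
            for a, b in rng.integers(0, 800_000, size=(200, 2))
        ]
        got = chiapet_targets(regions, interactions, genes).targets
        oracle = _chiapet_bruteforce(regions, interactions, genes, 2_500)
        assert got == oracle

    def test_symmetric_in_anchor_order(self):
        region = GenomicInterval("chr1", 100_000, 100_200, name="r1")
        gene = GeneModel("gA", "chr1", "+", 300_000, 310_000)
        a = GenomicInterval("chr1", 99_950, 100_150)
        b = GenomicInterval("chr1", 298_000, 298_500)
        out1 = chiapet_targets([region], [InteractionPair(a, b)], [gene])
        out2 = chiapet_targets([region], [InteractionPair(b, a)], [gene])
        assert out1.targets == out2.targets


class TestGainedInteractionTargets:
    def _assign(self, targets, method="chiapet"):
        return TargetAssignment(method=method, targets=targets)

    def test_identical_assignments_gain_nothing(self):
        a = self._assign({"r1": {"gA"}, "r2": {"gB"}})
        assert gained_interaction_targets(a, a) == set()

    def test_one_new_gene_detected(self):
        a = self._assign({"r1": {"gA"}})
        b = self._assign({"r1": {"gA"}, "r2": {"gC"}})
        assert gained_interaction_targets(a, b) == {"gC"}

    def test_matches_set_difference_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        def random_assign():
            return self._assign({
                f"r{i}": set(rng.choice(genes, size=rng.integers(0, 4),
                                        replace=False))
                for i in range(20)
            })
        a, b = random_assign(), random_assign()
        got = gained_interaction_targets(a, b)
        assert got == b.all_genes() - a.all_genes()

    def test_method_mismatch_rejected(self):
        a = self._assign({"r1": {"gA"}}, method="nearest")
        b = self._assign({"r1": {"gA"}})
        with pytest.raises(ValueError):
            gained_interaction_targets(a, b)


class TestExpressionChangeTest:
    def test_too_few_targets_rejected(self):
        a = _expr({f"g{i}": 1.0 for i in range(10)})
        b = _expr({f"g{i}": 2.0 for i in range(10)})
        with pytest.raises(ValueError, match="3"):
            expression_change_test({"g0", "g1"}, a, b)

    def test_empty_background_rejected(self):
        a = _expr({f"g{i}": 1.0 for i in range(4)})
        b = _expr({f"g{i}": 2.0 for i in range(4)})
        with pytest.raises(ValueError, match="background"):
            expression_change_test({"g0", "g1", "g2", "g3"}, a, b)

    def test_upward_shift_detected_with_direction(self, rng):
        n = 200
        a_vals = rng.lognormal(1, 0.5, size=n)
        b_vals = a_vals.copy()
        b_vals[:30] *= 8.0
        ids = [f"g{i}" for i in range(n)]
        res = expression_change_test(
            set(ids[:30]), _expr(zip(ids, a_vals)), _expr(zip(ids, b_vals))
        )
        assert res.p_value < 1e-4
        assert res.direction == "up"
        assert res.statistic > 0
        assert res.n_targets == 30

    def test_invariant_to_gene_order_and_missing_values(self, rng):
        ids = [f"g{i}" for i in range(50)]
        a_vals = rng.lognormal(1, 0.5, size=50)
        b_vals = a_vals * rng.lognormal(0, 0.3, size=50)
        a, b = _expr(zip(ids, a_vals)), _expr(zip(ids, b_vals))
        res1 = expression_change_test(set(ids[:10]), a, b)
        # add genes carrying missing values on either side
        a2 = _expr(list(zip(ids, a_vals)) + [("gx", math.nan), ("gy", 2.0)])
        b2 = _expr(list(zip(ids, b_vals)) + [("gx", 1.0), ("gy", math.nan)])
        res2 = expression_change_test(set(ids[:10]) | {"gx", "gy"}, a2, b2)
        assert res1.p_value == res2.p_value
        assert res1.statistic == res2.statistic

    def test_pvalue_matches_exhaustive_permutation_null(self):
        """On small samples without ties, the reported p-value equals the
        exact tail probability of the Wilcoxon permutation null."""
        values = np.array([0.3, -1.2, 2.1, 0.8, -0.4, 1.5, -2.0, 0.05])
        ids = [f"g{i}" for i in range(8)]
        a = _expr({g: 1.0 for g in ids})
        # with A = 1 and pseudocount 1, log2((B+1)/2) reproduces `values`
        b = _expr({g: 2.0 ** v * 2.0 - 1.0 for g, v in zip(ids, values)})

        def u_stat(target_idx):
            t = values[list(target_idx)]
            bg = np.delete(values, list(target_idx))
            return sum(x > y for x in t for y in bg)

        all_splits = list(itertools.combinations(range(8), 3))
        u_null = np.array([u_stat(s) for s in all_splits])
        for target_idx in all_splits:
            res = expression_change_test({ids[i] for i in target_idx}, a, b)
            p_perm = np.mean(u_null >= u_stat(target_idx))
            assert res.p_value == pytest.approx(p_perm, abs=1e-12)


class TestLineageActivationFraction:
    REGIONS = [
        GenomicInterval("chr1", 1_000 * i + 100, 1_000 * i + 300, name=f"r{i}")
        for i in range(100)
    ]

    def test_no_calls_gives_zero(self):
        calls = {"NPC": [False] * 100, "endo": [False] * 100}
        assert lineage_activation_fraction(self.REGIONS, calls) == {
            "NPC": 0.0, "endo": 0.0,
        }

    def test_additional_fraction_accounting(self):
        npc = [i < 9 for i in range(100)]
        # endomesoderm re-calls 5 NPC regions plus 20 new ones
        endo = [i in range(4, 29) for i in range(100)]
        out = lineage_activation_fraction(
            self.REGIONS, {"NPC": npc, "endomesoderm": endo}
        )
        assert out == {"NPC": 0.09, "endomesoderm": 0.20}

    def test_matches_counting_oracle(self, rng):
        calls = {
            "l1": rng.random(100) < 0.3,
            "l2": rng.random(100) < 0.3,
        }
        out = lineage_activation_fraction(self.REGIONS, calls)
        first = calls["l1"]
        second = calls["l2"] & ~calls["l1"]
        assert out["l1"] == first.sum() / 100
        assert out["l2"] == second.sum() / 100

    def test_incomplete_calls_rejected(self):
        with pytest.raises(ValueError):
            lineage_activation_fraction(self.REGIONS, {"l1": [True] * 5})
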