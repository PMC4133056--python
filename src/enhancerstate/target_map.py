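"""Target-gene assignment for regulatory regions and expression-change tests.

Two assignment routes mirror the usual practice: nearest annotated TSS
(one gene per region) and ChIA-PET interactions (a region targets a gene
when one interaction anchor overlaps the region and the mate anchor
overlaps the gene's promoter window). Expression changes of a target set
between two cell states are tested against a background gene set with a
one-sided Wilcoxon rank-sum test on log2 fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core_io import GeneModel, GenomicInterval, InteractionPair, nearest_tss_distance
from .transcription_quant import ExpressionTable

__all__ = [
    "TargetAssignment",
    "ExpressionChangeResult",
    "nearest_gene_targets",
    "chiapet_targets",
    "gained_interaction_targets",
    "expression_change_test",
    "lineage_activation_fraction",
]


@dataclass
class TargetAssignment:
    """region name -> set of target gene_ids, with the method recorded."""

    method: str  # "nearest" | "chiapet"
    targets: dict[str, set[str]]
    cell_state: str = ""

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tgene_id\n")
            for region in sorted(self.targets):
                for g in sorted(self.targets[region]):
                    fh.write(f"{region}\t{g}\n")


def _region_key(region: GenomicInterval, index: int) -> str:
    return region.name or f"region_{index}"


def nearest_gene_targets(
    regions: Sequence[GenomicInterval], genes: Sequence[GeneModel],
    cell_state: str = "",
) -> TargetAssignment:
    """Map every region to the gene with the nearest TSS (ties by gene_id)."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    targets = {
        _region_key(r, i): {nearest_tss_distance(r, genes)[1]}
        for i, r in enumerate(regions)
    }
    return TargetAssignment(method="nearest", targets=targets, cell_state=cell_state)


def _build_tree(items: Sequence[tuple[str, int, int, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, payload in items:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)
    return trees


def chiapet_targets(
    regions: Sequence[GenomicInterval],
    interactions: Sequence[InteractionPair],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2500,
    cell_state: str = "",
) -> TargetAssignment:
    """Assign target genes via chromatin interactions.

    Gene g is a target of region r iff some interaction has one anchor
    overlapping r by >= 1 bp and the other anchor overlapping the promoter
    window [tss - promoter_halfwidth, tss + promoter_halfwidth).
    """
    region_trees = _build_tree(
        [(r.chrom, r.start, r.end, _region_key(r, i)) for i, r in enumerate(regions)]
    )
    promoter_trees = _build_tree(
        [
            (g.chrom, max(0, g.tss - promoter_halfwidth), g.tss + promoter_halfwidth,
             g.gene_id)
            for g in genes
        ]
    )
    targets: dict[str, set[str]] = {
        _region_key(r, i): set() for i, r in enumerate(regions)
    }

    def hits(trees: dict[str, IntervalTree], a: GenomicInterval) -> set:
        tree = trees.get(a.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(a.start, a.end)}

    for pair in interactions:
        for a, b in ((pair.anchor1, pair.anchor2), (pair.anchor2, pair.anchor1)):
            region_hits = hits(region_trees, a)
            if not region_hits:
                continue
            gene_hits = hits(promoter_trees, b)
            for rname in region_hits:
                targets[rname] |= gene_hits
    return TargetAssignment(method="chiapet", targets=targets, cell_state=cell_state)


def gained_interaction_targets(
    assign_state_a: TargetAssignment, assign_state_b: TargetAssignment
) -> set[str]:
    """Genes targeted (by any region) in state B but by none in state A."""
    if assign_state_a.method != "chiapet" or assign_state_b.method != "chiapet":
        raise ValueError("gained-interaction comparison requires chiapet assignments")
    return assign_state_b.all_genes() - assign_state_a.all_genes()


@dataclass
class ExpressionChangeResult:
    """Outcome of the target-set expression-change test.

    ``statistic`` is the centered Mann-Whitney U (U - n1*n2/2); its sign
    gives the direction (positive = targets shifted up vs background).
    """

    n_targets: int
    statistic: float
    p_value: float
    direction: str  # up | down | none
    test_name: str = "wilcoxon-rank-sum-one-sided"
    log2fc_targets: np.ndarray | None = field(default=None, repr=False)


def _log2_changes(
    genes: set[str],
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    pseudocount: float,
) -> np.ndarray:
    vals = []
    for g in sorted(genes):
        if g not in expr_a or g not in expr_b:
            continue
        a, b = expr_a[g], expr_b[g]
        if math.isnan(a) or math.isnan(b):
            continue
        vals.append(math.log2((b + pseudocount) / (a + pseudocount)))
    return np.asarray(vals)


def expression_change_test(
    target_genes: set[str],
    expr_state_a: ExpressionTable,
    expr_state_b: ExpressionTable,
    background_genes: set[str] | None = None,
    pseudocount: float = 1.0,
    alternative: str = "greater",
) -> ExpressionChangeResult:
    """One-sided Wilcoxon rank-sum of target log2 fold changes vs background.

    Per-gene change = log2((RPKM_B + c)/(RPKM_A + c)) with pseudocount c
    (default 1). Genes with a missing value in either state are dropped.
    When ``background_genes`` is None, all genes valid in both states minus
    the targets are used. Requires >= 3 valid targets and a non-empty
    background.
    """
    if background_genes is None:
        background_genes = (
            expr_state_a.valid_genes() & expr_state_b.valid_genes()
        ) - set(target_genes)
    background_genes = set(background_genes) - set(target_genes)
    t = _log2_changes(set(target_genes), expr_state_a, expr_state_b, pseudocount)
    b = _log2_changes(background_genes, expr_state_a, expr_state_b, pseudocount)
    if t.size < 3:
        raise ValueError(f"need >= 3 valid target genes, got {t.size}")
    if b.size == 0:
        raise ValueError("background gene set is empty after filtering")
    res = stats.mannwhitneyu(t, b, alternative=alternative)
    centered = float(res.statistic) - t.size * b.size / 2.0
    if centered > 0:
        direction = "up"
    elif centered < 0:
        direction = "down"
    else:
        direction = "none"
    return ExpressionChangeResult(
        n_targets=int(t.size),
        statistic=centered,
        p_value=float(res.pvalue),
        direction=direction,
        log2fc_targets=t,
    )


def lineage_activation_fraction(
    regions: Sequence[GenomicInterval],
    activation_calls: Mapping[str, Sequence[bool]],
) -> dict[str, float]:
    """Fraction of regions first activated in each lineage.

    ``activation_calls`` maps lineage name -> boolean vector aligned with
    ``regions``; lineages are processed in mapping order and a region counts
    only for the first lineage in which it is called active (so a later
    lineage reports the *additional* activated fraction).
    """
    n = len(regions)
    claimed = np.zeros(n, dtype=bool)
    fractions: dict[str, float] = {}
    for lineage, calls in activation_calls.items():
        calls = np.asarray(calls, dtype=bool)
        if calls.shape != (n,):
            raise ValueError(f"lineage {lineage}: calls must cover all regions")
        new = calls & ~claimed
        fractions[lineage] = float(new.sum() / n) if n else 0.0
        claimed |= new
    return fractions
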