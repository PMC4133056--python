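#!/usr/bin/env python
"""Map silenced-enhancer target genes and test lineage-specific activation.

Uses the silenced-enhancer regions called by script 02. Assigns target
genes through ChIA-PET interactions in the baseline (ESC) and
differentiated (NPC) states, identifies genes that gained an interaction,
and tests whether those genes are upregulated after differentiation
(one-sided Wilcoxon rank-sum of log2 fold changes vs all other genes).
Also reports the fraction of distal TFBSs first activated (H3K4me1/2
gain) per lineage.

Output: results/04_targets.tsv, results/04_activation_summary.tsv.
"""

import argparse
from pathlib import Path

from enhancerstate.core_io import read_bed
from enhancerstate.pipeline import distal_filter, load_inputs
from enhancerstate.target_map import (
    chiapet_targets,
    expression_change_test,
    gained_interaction_targets,
    lineage_activation_fraction,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    inputs = load_inputs(args.workdir / "fixtures")
    silenced = read_bed(args.results / "02_silenced_enhancers.bed")

    esc = chiapet_targets(silenced, inputs.interactions_esc, inputs.genes,
                          cell_state="ESC")
    npc = chiapet_targets(silenced, inputs.interactions_npc, inputs.genes,
                          cell_state="NPC")
    gained = gained_interaction_targets(esc, npc)

    args.results.mkdir(parents=True, exist_ok=True)
    with open(args.results / "04_targets.tsv", "w") as fh:
        fh.write("region\tgene_id\tstate\n")
        for state, assign in (("ESC", esc), ("NPC", npc)):
            for region in sorted(assign.targets):
                for g in sorted(assign.targets[region]):
                    fh.write(f"{region}\t{g}\t{state}\n")

    lines = []
    if len(gained) >= 3:
        res = expression_change_test(gained, inputs.expr_esc, inputs.expr_npc)
        lines.append(("gained_target_genes", len(gained)))
        lines.append(("wilcoxon_p_value", f"{res.p_value:.3g}"))
        lines.append(("direction", res.direction))
        print(f"{len(gained)} genes gained a promoter interaction in NPC")
        print(f"expression change vs background: p = {res.p_value:.3g} "
              f"({res.direction}regulated)")
    else:
        res = None
        lines.append(("gained_target_genes", len(gained)))
        print(f"only {len(gained)} gained targets; too few to test")

    distal = distal_filter(inputs.tfbs, inputs.genes)
    idx = {r.name: i for i, r in enumerate(inputs.tfbs)}
    fractions = lineage_activation_fraction(
        distal,
        {
            lineage: [bool(calls[idx[r.name]]) for r in distal]
            for lineage, calls in inputs.activation_calls.items()
        },
    )
    for lineage, f in fractions.items():
        lines.append((f"activated_fraction_{lineage}", f"{f:.4f}"))
        print(f"distal TFBSs first activated in {lineage}: {100 * f:.1f}%")

    with open(args.results / "04_activation_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        for k, v in lines:
            fh.write(f"{k}\t{v}\n")


if __name__ == "__main__":
    main()
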