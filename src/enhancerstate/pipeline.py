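"""End-to-end orchestration: simulate -> write -> read back -> matrices ->
cluster -> characterize -> transcription -> targets -> differential test.

The driver deliberately round-trips the simulated data through the standard
text formats (BED/bedGraph/BEDPE/TSV) so a run exercises the same reader
code paths a real-data analysis would, and writes every product as a
deterministic TSV — two runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import core_io, signal_matrix, cluster_model, transcription_quant, target_map
from .cluster_model import CLUSTERING_MARKS
from .core_io import CoverageTrack, GenomicInterval
from .signal_matrix import SignalMatrix, compute_matrix, rpkm_normalize
from .synthetic_data import (
    MARKS,
    SimulatedStudy,
    SimulationConfig,
    combined_groseq,
    simulate_study,
    write_fixtures,
)

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "distal_filter",
    "build_matrices",
    "load_inputs",
]

DISTAL_MIN_TSS_DISTANCE = 2000


def distal_filter(
    regions: list[GenomicInterval],
    genes,
    min_distance: int = DISTAL_MIN_TSS_DISTANCE,
) -> list[GenomicInterval]:
    """Regions whose center lies more than ``min_distance`` from every TSS."""
    return [
        r for r in regions
        if core_io.nearest_tss_distance(r, genes)[0] > min_distance
    ]


def build_matrices(
    regions: list[GenomicInterval],
    raw_tracks: Mapping[str, CoverageTrack],
    flank: int = 2000,
    bin_size: int = 100,
    cap: float | None = None,
) -> dict[str, SignalMatrix]:
    """RPKM-normalize every track and compute region x bin matrices.

    GRO-seq strand tracks are summed into one bidirectional "GROseq" matrix
    (eRNA and nascent signal are read out strand-agnostically at regions).
    """
    tracks = dict(raw_tracks)
    if "GROseq_plus" in tracks and "GROseq_minus" in tracks:
        tracks["GROseq"] = combined_groseq(
            {"GROseq_plus": tracks.pop("GROseq_plus"),
             "GROseq_minus": tracks.pop("GROseq_minus")}
        )
    out: dict[str, SignalMatrix] = {}
    for mark, track in tracks.items():
        norm = rpkm_normalize(track) if not track.normalized else track
        m = compute_matrix(regions, norm, flank=flank, bin_size=bin_size, cap=cap)
        m.mark_name = mark
        out[mark] = m
    return out


@dataclass
class StudyInputs:
    """A simulated study as read back from its standard-format files."""

    genes: list
    tfbs: list[GenomicInterval]
    truth_labels: dict[str, str]
    raw_tracks: dict[str, CoverageTrack]
    tracks_npc: dict[str, CoverageTrack]
    interactions_esc: list
    interactions_npc: list
    expr_esc: transcription_quant.ExpressionTable
    expr_npc: transcription_quant.ExpressionTable
    activation_calls: dict[str, np.ndarray]


def load_inputs(fixdir, bin_size: int = 100) -> StudyInputs:
    """Read a fixture directory written by
    :func:`~enhancerstate.synthetic_data.write_fixtures` back into memory
    through the standard-format readers."""
    fixdir = Path(fixdir)
    genes = core_io.read_genes(fixdir / "genes.tsv")
    tfbs = core_io.read_bed(fixdir / "tfbs.bed")
    truth_labels: dict[str, str] = {}
    with open(fixdir / "truth_labels.tsv") as fh:
        next(fh)
        for line in fh:
            name, label = line.rstrip("\n").split("\t")
            truth_labels[name] = label
    libsizes = {}
    with open(fixdir / "library_sizes.tsv") as fh:
        next(fh)
        for line in fh:
            name, n = line.split("\t")
            libsizes[name] = int(n)
    raw_tracks = {
        mark: core_io.read_bedgraph(
            fixdir / f"{mark}.bedgraph", bin_size, libsizes[mark]
        )
        for mark in list(MARKS) + ["GROseq_plus", "GROseq_minus"]
    }
    tracks_npc = {
        mark: core_io.read_bedgraph(
            fixdir / f"{mark}_NPC.bedgraph", bin_size, libsizes[f"{mark}_NPC"]
        )
        for mark in ("H3K4me1", "H3K4me2")
        if (fixdir / f"{mark}_NPC.bedgraph").exists()
    }
    calls: dict[str, np.ndarray] = {}
    with open(fixdir / "activation_calls.tsv") as fh:
        lineages = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
    for j, lineage in enumerate(lineages):
        calls[lineage] = np.array([row[j] == "1" for row in rows])
    return StudyInputs(
        genes=genes,
        tfbs=tfbs,
        truth_labels=truth_labels,
        raw_tracks=raw_tracks,
        tracks_npc=tracks_npc,
        interactions_esc=core_io.read_interactions(fixdir / "interactions_esc.bedpe"),
        interactions_npc=core_io.read_interactions(fixdir / "interactions_npc.bedpe"),
        expr_esc=transcription_quant.ExpressionTable.read_tsv(
            fixdir / "expression_esc.tsv"
        ),
        expr_npc=transcription_quant.ExpressionTable.read_tsv(
            fixdir / "expression_npc.tsv"
        ),
        activation_calls=calls,
    )


@dataclass
class PipelineResult:
    """Everything a full run produces, plus where it was written."""

    study: SimulatedStudy
    regions: list[GenomicInterval]          # distal TFBSs, clustered set
    matrices: dict[str, SignalMatrix]
    model: cluster_model.ClusterModel
    signatures: list[cluster_model.ClusterSignature]
    silenced_regions: list[GenomicInterval]
    expression: transcription_quant.ExpressionTable
    hmc_groseq_correlation: float
    targets_esc: target_map.TargetAssignment
    targets_npc: target_map.TargetAssignment
    gained_genes: set[str]
    change_result: target_map.ExpressionChangeResult | None
    lineage_fractions: dict[str, float]
    outdir: Path | None = None


def _write_signatures(signatures, path) -> None:
    marks = sorted(signatures[0].core_means) if signatures else []
    with open(path, "w") as fh:
        fh.write("cluster\tn\tlabel\t"
                 + "\t".join(f"{m}_mean\t{m}_flag" for m in marks) + "\n")
        for s in signatures:
            cells = [str(s.cluster_id), str(s.n_members), s.label]
            for m in marks:
                cells += [f"{s.core_means[m]:.6g}", s.flags[m]]
            fh.write("\t".join(cells) + "\n")


def run_pipeline(
    config: SimulationConfig,
    outdir,
    cap: float | None = None,
    K: int = 10,
    n_restarts: int = 10,
    trend_window: int = 100,
) -> PipelineResult:
    """Simulate a study, write it to disk, read it back, and run every
    analysis stage, writing deterministic TSV outputs under ``outdir``."""
    outdir = Path(outdir)
    fixdir = outdir / "fixtures"
    study = simulate_study(config)
    paths = write_fixtures(study, fixdir)

    # ---- read everything back through the standard-format readers
    inputs = load_inputs(fixdir, bin_size=config.bin_size)
    genes, tfbs = inputs.genes, inputs.tfbs
    raw_tracks = inputs.raw_tracks
    inter_esc, inter_npc = inputs.interactions_esc, inputs.interactions_npc

    # ---- distal TFBSs, signal matrices, clustering, signatures
    distal = distal_filter(tfbs, genes)
    matrices = build_matrices(distal, raw_tracks, cap=cap)
    features = cluster_model.FeatureMatrix.from_matrices(
        [matrices[m] for m in CLUSTERING_MARKS]
    )
    model = cluster_model.kmeans_cluster(
        features, K=K, seed=config.seed, n_restarts=n_restarts
    )
    signatures = cluster_model.characterize_clusters(model, matrices)
    silenced = cluster_model.silenced_enhancer_regions(signatures, model)

    # ---- transcription: gene RPKM and the sorted 5hmC/GROseq trend
    expression = transcription_quant.expression_table(
        genes, raw_tracks["GROseq_plus"], raw_tracks["GROseq_minus"]
    )
    hmc_core = matrices["5hmC"].core_means(1000)
    gro_core = matrices["GROseq"].core_means(2000)
    corr = transcription_quant.sorted_correlation(
        hmc_core, gro_core, window=trend_window,
        names=[r.name for r in distal],
    )

    # ---- targets and the gained-interaction expression test
    targets_esc = target_map.chiapet_targets(
        silenced, inter_esc, genes, cell_state="ESC")
    targets_npc = target_map.chiapet_targets(
        silenced, inter_npc, genes, cell_state="NPC")
    gained = target_map.gained_interaction_targets(targets_esc, targets_npc)
    change = None
    if len(gained) >= 3:
        change = target_map.expression_change_test(
            gained, study.expr_esc, study.expr_npc)

    tfbs_index = {r.name: i for i, r in enumerate(study.tfbs)}
    fractions = target_map.lineage_activation_fraction(
        distal,
        {
            lineage: [
                bool(study.activation_calls[lineage][tfbs_index[r.name]])
                for r in distal
            ]
            for lineage in study.activation_calls
        },
    )

    # ---- deterministic outputs
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("region\tcluster\n")
        for r, a in zip(distal, model.assignments):
            fh.write(f"{r.name}\t{a}\n")
    _write_signatures(signatures, outdir / "signatures.tsv")
    core_io.write_bed(silenced, outdir / "silenced_enhancers.bed")
    expression.write_tsv(outdir / "expression_groseq.tsv")
    targets_esc.write_tsv(outdir / "targets_esc.tsv")
    targets_npc.write_tsv(outdir / "targets_npc.tsv")
    summary = {
        "n_tfbs": len(tfbs),
        "n_distal_tfbs": len(distal),
        "n_clusters": K,
        "n_silenced_regions": len(silenced),
        "hmc_groseq_sorted_correlation": None if math.isnan(corr) else round(corr, 6),
        "n_gained_target_genes": len(gained),
        "gained_upregulation_p": None if change is None else round(change.p_value, 6),
        "gained_direction": None if change is None else change.direction,
        "lineage_activation_fractions": {
            k: round(v, 6) for k, v in fractions.items()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        study=study,
        regions=distal,
        matrices=matrices,
        model=model,
        signatures=signatures,
        silenced_regions=silenced,
        expression=expression,
        hmc_groseq_correlation=corr,
        targets_esc=targets_esc,
        targets_npc=targets_npc,
        gained_genes=gained,
        change_result=change,
        lineage_fractions=fractions,
        outdir=outdir,
    )
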