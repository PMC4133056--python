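"""Synthetic miniature epigenome with known ground truth.

Generates, from one integer seed, everything the pipeline consumes: a short
chromosome with non-overlapping genes, TFBSs drawn from labeled chromatin
archetypes (active enhancer, silenced enhancer, promoter-like, polycomb,
...), per-mark coverage tracks (Poisson background plus Gaussian enrichment
bumps with lognormal peak-height jitter), strand-specific nascent
transcription with promoter pausing and bidirectional eRNA at active
enhancers only, promoter-anchored chromatin interactions for a subset of
silenced enhancers, and a differentiation step in which a lineage-specific
subset of silenced enhancers gains activating marks and upregulates its
target genes.

The defining archetype is the *silenced enhancer*: 5hmC and 5fC enrichment
with zero H3K4me1, zero H3K27ac and zero eRNA. The generator plants it so
that every pipeline stage — distal filtering, clustering, signature
labeling, target mapping, differential expression — can be checked against
the planted truth.

Everything is deterministic: identical config + seed gives byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    InteractionPair,
    write_bed,
    write_bedgraph,
    write_genes,
    write_interactions,
)
from .transcription_quant import ExpressionTable, derive_windows

__all__ = [
    "MARKS",
    "ArchetypeSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "default_archetypes",
    "simulate_genome",
    "simulate_tracks",
    "simulate_interactions",
    "simulate_activation",
    "simulate_differentiation",
    "simulate_study",
    "combined_groseq",
    "write_fixtures",
]

#: ChIP-like marks emitted as one track each; GRO-seq adds two strand tracks.
MARKS = (
    "5hmC", "5mC", "5fC", "Tet1",
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K27me3", "PolII",
)

SILENCED = "silenced-enhancer"


@dataclass
class ArchetypeSpec:
    """One chromatin archetype: per-mark peak amplitudes and shapes.

    ``amplitudes`` are expected reads per bin at the bump peak;
    ``shapes`` per mark are ``point`` (single bump at the center),
    ``bimodal`` (two flanking bumps, nucleosome-style), or ``broad``
    (wide domain-like bump); unspecified marks default to ``point``.
    ``proximal`` archetypes are placed within 2 kb of a TSS, everything
    else strictly distal.
    """

    name: str
    amplitudes: dict[str, float]
    erna_amplitude: float = 0.0
    count: int = 60
    shapes: dict[str, str] = field(default_factory=dict)
    proximal: bool = False

    def amp(self, mark: str) -> float:
        return self.amplitudes.get(mark, 0.0)

    def shape(self, mark: str) -> str:
        return self.shapes.get(mark, "point")


def default_archetypes(count: int = 60) -> list[ArchetypeSpec]:
    """Ten archetypes emulating the chromatin states seen at TF binding
    sites: promoter-like, active/weak/genic enhancers, the 5hmC/5fC-only
    silenced enhancer, an H3K4me1-only poised enhancer, polycomb and
    bivalent states, a Tet1-bound hydroxymethylated state, and a primed
    H3K4me2-only state."""
    A = ArchetypeSpec
    return [
        A("promoter-like",
          {"H3K4me3": 40, "H3K4me2": 20, "H3K4me1": 5, "H3K27ac": 10,
           "PolII": 30, "Tet1": 5},
          erna_amplitude=8.0, count=count, proximal=True),
        A(SILENCED,
          {"5hmC": 30, "5fC": 20, "Tet1": 10},
          erna_amplitude=0.0, count=count),
        A("active-enhancer",
          {"H3K4me1": 25, "H3K4me2": 10, "H3K27ac": 35, "PolII": 8,
           "Tet1": 5, "5hmC": 2.5},
          erna_amplitude=15.0, count=count,
          shapes={"H3K4me1": "bimodal", "H3K27ac": "bimodal"}),
        A("weak-active-enhancer",
          {"H3K27ac": 20, "H3K4me2": 2.5, "5hmC": 5, "PolII": 2.5},
          erna_amplitude=6.0, count=count),
        A("poised-enhancer",
          {"H3K4me1": 25, "5fC": 15, "5hmC": 10, "Tet1": 5},
          erna_amplitude=0.0, count=count,
          shapes={"H3K4me1": "bimodal"}),
        A("polycomb",
          {"H3K27me3": 30, "5hmC": 2.5},
          erna_amplitude=0.0, count=count,
          shapes={"H3K27me3": "broad"}),
        A("bivalent",
          {"H3K4me3": 20, "H3K27me3": 25, "Tet1": 2.5},
          erna_amplitude=0.0, count=count),
        A("genic-enhancer",
          {"H3K4me1": 15, "H3K4me3": 15, "5hmC": 5, "PolII": 8},
          erna_amplitude=6.0, count=count),
        A("tet1-bound",
          {"Tet1": 30, "5hmC": 15, "H3K4me1": 8, "5fC": 5},
          erna_amplitude=2.5, count=count,
          shapes={"5hmC": "bimodal"}),
        A("primed-k4me2",
          {"H3K4me2": 25, "5hmC": 4, "Tet1": 5},
          erna_amplitude=4.0, count=count),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the miniature epigenome; defaults are the study
    conditions used throughout the tests and analyses."""

    seed: int = 0
    chrom: str = "chrS"
    chrom_size: int = 5_000_000
    bin_size: int = 100
    # genes
    n_genes: int = 60
    gene_length_min: int = 5_000
    gene_length_max: int = 30_000
    expressed_fraction: float = 0.8
    gene_rate_log_mean: float = math.log(4.0)  # lognormal of sense reads/bin
    gene_rate_sigma: float = 0.8
    pausing_factor: float = 4.0     # promoter-pausing bump vs gene-body rate
    # TFBS placement
    tfbs_width: int = 200
    tfbs_spacing: int = 5_000
    distal_margin: int = 3_000      # distal sites placed > this from any TSS
    proximal_max_offset: int = 1_800
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    # tracks
    background_rate: float = 0.2    # Poisson reads per bin
    height_sigma: float = 0.3       # lognormal sigma of peak-height jitter
    bump_sd: int = 300
    bimodal_offset: int = 500
    broad_sd: int = 900
    erna_offset: int = 150          # divergent eRNA bump offset per strand
    mC_base_rate: float = 2.0       # genome-wide 5mC plateau
    mC_dip_depth: float = 0.8       # fractional 5mC dip at TFBS cores
    # interactions & differentiation
    wired_fraction: float = 0.5     # silenced enhancers wired in the ESC state
    promoter_anchor_halfwidth: int = 1_000
    lineage_fractions: dict[str, float] = field(
        default_factory=lambda: {"NPC": 0.09, "endomesoderm": 0.20}
    )
    activation_fold: float = 4.0
    expr_noise_sigma: float = 0.15
    activated_k4me1_amp: float = 4.0
    activated_k4me2_amp: float = 3.0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if not 0 <= self.wired_fraction <= 1:
            raise ValueError("wired_fraction must be in [0, 1]")
        if not 0 <= self.expressed_fraction <= 1:
            raise ValueError("expressed_fraction must be in [0, 1]")
        for lineage, f in self.lineage_fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"lineage fraction {lineage} must be in [0, 1]")
        if any(a.count < 0 for a in self.archetypes):
            raise ValueError("archetype counts must be >= 0")
        for a in self.archetypes:
            if a.name == SILENCED:
                if a.amp("5hmC") <= 0 or a.amp("5fC") <= 0:
                    raise ValueError("silenced archetype requires 5hmC and 5fC > 0")
                if a.amp("H3K4me1") or a.amp("H3K27ac") or a.erna_amplitude:
                    raise ValueError(
                        "silenced archetype must lack H3K4me1/H3K27ac/eRNA"
                    )

    @property
    def n_tfbs(self) -> int:
        return sum(a.count for a in self.archetypes)

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *tags])


# stream tags so each stage draws from an independent deterministic stream
_T_GENES, _T_EXPR, _T_PLACE, _T_TRACK, _T_INTER, _T_ACT, _T_DIFF = range(1, 8)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], list[str]]:
    """Place genes and archetype-labeled TFBSs.

    Genes are laid out one per equal slot (no overlap, generous flanks).
    Proximal archetypes land within ``proximal_max_offset`` of a TSS; all
    other archetypes land farther than ``distal_margin`` from every TSS and
    outside gene spans, at least ``tfbs_spacing`` apart so the +/-2 kb
    profile windows stay essentially independent. Returns
    ``(genes, tfbs, labels)`` with TFBSs named ``tfbs_####`` in coordinate
    order and ``labels`` aligned with them.
    """
    rng = config.rng(_T_GENES)
    margin = 50_000
    span = config.chrom_size - 2 * margin
    slot = span // config.n_genes
    if slot < config.gene_length_max + 2 * config.distal_margin:
        raise ValueError("genome too small for the requested gene count")
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        lo = margin + i * slot + config.distal_margin
        hi = margin + (i + 1) * slot - config.distal_margin - length
        start = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (start, start + length) if strand == "+" else (start + length, start)
        genes.append(GeneModel(f"gene_{i:03d}", config.chrom, strand, tss, tts))

    place_rng = config.rng(_T_PLACE)
    half = config.tfbs_width // 2

    # proximal placements: cycle over genes
    proximal_specs = [a for a in config.archetypes if a.proximal]
    distal_specs = [a for a in config.archetypes if not a.proximal]
    placements: list[tuple[int, str]] = []  # (center, archetype name)
    gene_cycle = 0
    for spec in proximal_specs:
        for _ in range(spec.count):
            g = genes[gene_cycle % len(genes)]
            gene_cycle += 1
            off = int(place_rng.integers(-config.proximal_max_offset,
                                         config.proximal_max_offset + 1))
            placements.append((g.tss + off, spec.name))

    # distal placements: slots in the complement of gene spans +/- margins
    blocked = sorted(
        (g.start - config.distal_margin, g.end + config.distal_margin) for g in genes
    )
    allowed: list[tuple[int, int]] = []
    cursor = margin
    for s, e in blocked:
        if s - cursor >= config.tfbs_spacing:
            allowed.append((cursor, s))
        cursor = max(cursor, e)
    if config.chrom_size - margin - cursor >= config.tfbs_spacing:
        allowed.append((cursor, config.chrom_size - margin))
    slots: list[int] = []
    for a, b in allowed:
        pos = a + config.tfbs_spacing // 2
        while pos <= b - config.tfbs_spacing // 2:
            slots.append(pos)
            pos += config.tfbs_spacing
    n_distal = sum(a.count for a in distal_specs)
    if len(slots) < n_distal:
        raise ValueError(
            f"genome too small: {len(slots)} distal slots for {n_distal} TFBSs"
        )
    chosen = place_rng.permutation(len(slots))[:n_distal]
    jitter = place_rng.integers(-800, 801, size=n_distal)
    k = 0
    for spec in distal_specs:
        for _ in range(spec.count):
            placements.append((int(slots[chosen[k]] + jitter[k]), spec.name))
            k += 1

    placements.sort()
    tfbs = [
        GenomicInterval(config.chrom, c - half, c + half, ".", f"tfbs_{i:04d}")
        for i, (c, _) in enumerate(placements)
    ]
    labels = [name for _, name in placements]
    return genes, tfbs, labels


def simulate_gene_rates(
    genes: Sequence[GeneModel], config: SimulationConfig
) -> dict[str, float]:
    """Sense-strand gene-body transcription rate (reads/bin) per gene; a
    configured fraction of genes is expressed, the rest rate 0."""
    rng = config.rng(_T_EXPR)
    expressed = rng.random(len(genes)) < config.expressed_fraction
    rates = rng.lognormal(config.gene_rate_log_mean, config.gene_rate_sigma,
                          size=len(genes))
    return {
        g.gene_id: float(r) if ok else 0.0
        for g, r, ok in zip(genes, rates, expressed)
    }


def _bump(centers_bp: np.ndarray, heights: np.ndarray, sd: float,
          rate: np.ndarray, bin_size: int) -> None:
    """Add Gaussian bumps (peak ``heights`` reads/bin) to a rate vector."""
    n = rate.size
    reach = int(np.ceil(4 * sd / bin_size))
    bin_mid = bin_size / 2.0
    for c, h in zip(centers_bp, heights):
        j0 = max(0, int(c // bin_size) - reach)
        j1 = min(n, int(c // bin_size) + reach + 1)
        if j0 >= j1:
            continue
        x = np.arange(j0, j1) * bin_size + bin_mid
        rate[j0:j1] += h * np.exp(-((x - c) ** 2) / (2 * sd**2))


def _poisson_track(rate: np.ndarray, rng: np.random.Generator,
                   config: SimulationConfig) -> CoverageTrack:
    counts = rng.poisson(np.maximum(rate, 0.0)).astype(float)
    lib = max(1, int(counts.sum()))
    return CoverageTrack(
        bin_size=config.bin_size,
        chrom_vectors={config.chrom: counts},
        total_mapped_reads=lib,
        normalized=False,
    )


def simulate_tracks(
    genes: Sequence[GeneModel],
    tfbs: Sequence[GenomicInterval],
    labels: Sequence[str],
    config: SimulationConfig,
    gene_rates: Mapping[str, float] | None = None,
    extra_bumps: Mapping[str, Sequence[tuple[int, float]]] | None = None,
    state_tag: int = 0,
) -> dict[str, CoverageTrack]:
    """Simulate raw count tracks for every mark plus GROseq_plus/minus.

    Each ChIP-like mark is Poisson background plus archetype-specific
    Gaussian bumps with lognormal height jitter; 5mC is a genome-wide
    plateau with a dip at every TFBS core; GRO-seq carries sense-strand
    gene-body signal with a promoter-pausing bump and divergent bidirectional
    eRNA bumps at regions whose archetype has nonzero eRNA amplitude.
    ``extra_bumps`` maps a mark to additional (center, amplitude) bumps
    (used for lineage-activated H3K4me1/2 tracks). The declared library size
    of each track equals its realized total read count.
    """
    if gene_rates is None:
        gene_rates = simulate_gene_rates(genes, config)
    specs = {a.name: a for a in config.archetypes}
    n_bins = int(np.ceil(config.chrom_size / config.bin_size))
    b = config.bin_size
    centers = np.array([r.center for r in tfbs], dtype=float)

    tracks: dict[str, CoverageTrack] = {}
    for mi, mark in enumerate(MARKS):
        rng = config.rng(_T_TRACK, state_tag, mi)
        if mark == "5mC":
            rate = np.full(n_bins, config.mC_base_rate)
            # demethylated valley at every TFBS core
            dip = np.zeros(n_bins)
            _bump(centers, np.full(len(centers), config.mC_dip_depth),
                  config.bump_sd, dip, b)
            rate *= np.clip(1.0 - dip, 0.0, 1.0)
        else:
            rate = np.full(n_bins, config.background_rate)
            amps = np.array([specs[l].amp(mark) for l in labels])
            hit = np.flatnonzero(amps > 0)
            if hit.size:
                jit = rng.lognormal(-config.height_sigma**2 / 2,
                                    config.height_sigma, size=hit.size)
                for idx, j in zip(hit, jit):
                    spec = specs[labels[idx]]
                    h = amps[idx] * j
                    shape = spec.shape(mark)
                    if shape == "bimodal":
                        _bump(np.array([centers[idx] - config.bimodal_offset,
                                        centers[idx] + config.bimodal_offset]),
                              np.array([h, h]), config.bump_sd, rate, b)
                    elif shape == "broad":
                        _bump(np.array([centers[idx]]), np.array([h]),
                              config.broad_sd, rate, b)
                    else:
                        _bump(np.array([centers[idx]]), np.array([h]),
                              config.bump_sd, rate, b)
            if extra_bumps and mark in extra_bumps:
                for c, h in extra_bumps[mark]:
                    _bump(np.array([float(c)]), np.array([h]),
                          config.bump_sd, rate, b)
        tracks[mark] = _poisson_track(rate, rng, config)

    # GRO-seq, strand-split
    for si, strand in enumerate(("+", "-")):
        rng = config.rng(_T_TRACK, state_tag, 100 + si)
        rate = np.full(n_bins, config.background_rate / 2)
        for g in genes:
            r = gene_rates[g.gene_id]
            if r <= 0 or g.strand != strand:
                continue
            w = derive_windows(g).quant_window
            if w is not None:
                j0, j1 = w.start // b, int(np.ceil(w.end / b))
                rate[j0:j1] += r
            _bump(np.array([float(g.tss)]),
                  np.array([config.pausing_factor * r]), 200.0, rate, b)
        # divergent eRNA: plus-strand bump downstream, minus-strand upstream
        sign = 1 if strand == "+" else -1
        for idx, lab in enumerate(labels):
            e = specs[lab].erna_amplitude
            if e > 0:
                _bump(np.array([centers[idx] + sign * config.erna_offset]),
                      np.array([e]), config.bump_sd, rate, b)
        key = "GROseq_plus" if strand == "+" else "GROseq_minus"
        tracks[key] = _poisson_track(rate, rng, config)
    return tracks


def combined_groseq(tracks: Mapping[str, CoverageTrack]) -> CoverageTrack:
    """Strand-summed GRO-seq track (eRNAs are bidirectional, so the total
    nascent signal at a region is the sum over strands)."""
    plus, minus = tracks["GROseq_plus"], tracks["GROseq_minus"]
    if plus.normalized != minus.normalized:
        raise ValueError("strand tracks disagree on normalization")
    chroms = set(plus.chrom_vectors) | set(minus.chrom_vectors)
    vectors = {}
    for c in chroms:
        a = plus.chrom_vectors.get(c)
        bvec = minus.chrom_vectors.get(c)
        if a is None:
            vectors[c] = bvec.copy()
        elif bvec is None:
            vectors[c] = a.copy()
        else:
            n = max(len(a), len(bvec))
            v = np.zeros(n)
            v[: len(a)] += a
            v[: len(bvec)] += bvec
            vectors[c] = v
    return CoverageTrack(
        bin_size=plus.bin_size,
        chrom_vectors=vectors,
        total_mapped_reads=plus.total_mapped_reads + minus.total_mapped_reads,
        normalized=plus.normalized,
    )


def _silenced_indices(labels: Sequence[str]) -> list[int]:
    return [i for i, l in enumerate(labels) if l == SILENCED]


def assign_target_genes(
    tfbs: Sequence[GenomicInterval],
    labels: Sequence[str],
    genes: Sequence[GeneModel],
    gene_rates: Mapping[str, float],
    config: SimulationConfig,
) -> dict[str, str]:
    """Designate one expressed target gene per silenced enhancer (distinct
    while genes last, then cycling)."""
    rng = config.rng(_T_INTER, 0)
    expressed = [g for g in genes if gene_rates[g.gene_id] > 0]
    if not expressed:
        raise ValueError("no expressed genes eligible as interaction targets")
    order = rng.permutation(len(expressed))
    out: dict[str, str] = {}
    for j, idx in enumerate(_silenced_indices(labels)):
        out[tfbs[idx].name] = expressed[order[j % len(expressed)]].gene_id
    return out


def simulate_interactions(
    tfbs: Sequence[GenomicInterval],
    labels: Sequence[str],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    target_genes: Mapping[str, str],
    extra_wired: Sequence[str] = (),
) -> tuple[list[InteractionPair], dict[str, set[str]]]:
    """Wire silenced enhancers to their designated target promoters.

    The configured ``wired_fraction`` of silenced regions is wired in the
    baseline (ESC) state; ``extra_wired`` region names (e.g. the
    NPC-activated subset) are wired on top — gained interactions. Returns
    the pairs plus the ground-truth region -> target map.
    """
    rng = config.rng(_T_INTER, 1)
    sil = _silenced_indices(labels)
    if sil and not target_genes:
        raise ValueError("target genes required to wire silenced enhancers")
    gene_by_id = {g.gene_id: g for g in genes}
    n_wired = int(round(config.wired_fraction * len(sil)))
    base = [tfbs[i].name for i in
            (np.asarray(sil)[rng.permutation(len(sil))[:n_wired]] if sil else [])]
    wired = sorted(set(base) | set(extra_wired))
    by_name = {r.name: r for r in tfbs}
    hw = config.promoter_anchor_halfwidth
    pairs: list[InteractionPair] = []
    truth: dict[str, set[str]] = {}
    for rname in wired:
        r = by_name[rname]
        g = gene_by_id[target_genes[rname]]
        promoter = GenomicInterval(g.chrom, max(0, g.tss - hw), g.tss + hw)
        pairs.append(InteractionPair(
            GenomicInterval(r.chrom, r.start, r.end), promoter, support=2))
        truth[rname] = {g.gene_id}
    pairs.sort(key=lambda p: (p.anchor1.chrom, p.anchor1.start, p.anchor2.start))
    return pairs, truth


def simulate_activation(
    tfbs: Sequence[GenomicInterval],
    labels: Sequence[str],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> dict[str, np.ndarray]:
    """Per-lineage activation calls over all TFBSs.

    For each lineage (in config order) a fraction of the *distal* TFBSs —
    drawn preferentially from the silenced-enhancer archetype, then the
    remaining distal pool — gains activating H3K4me1/2 marks. A region
    activates in at most one lineage (the "additional fraction" accounting).
    """
    rng = config.rng(_T_ACT)
    n = len(tfbs)
    specs = {a.name: a for a in config.archetypes}
    distal = np.array([not specs[l].proximal for l in labels])
    n_distal = int(distal.sum())
    sil = [i for i in np.flatnonzero(distal) if labels[i] == SILENCED]
    rest = [i for i in np.flatnonzero(distal) if labels[i] != SILENCED]
    pool = list(np.asarray(sil)[rng.permutation(len(sil))]) + list(
        np.asarray(rest)[rng.permutation(len(rest))]
    )
    calls: dict[str, np.ndarray] = {}
    cursor = 0
    for lineage, frac in config.lineage_fractions.items():
        k = int(round(frac * n_distal))
        vec = np.zeros(n, dtype=bool)
        take = pool[cursor : cursor + k]
        vec[take] = True
        cursor += k
        calls[lineage] = vec
    return calls


def simulate_differentiation(
    expr_baseline: ExpressionTable,
    config: SimulationConfig,
    activated_target_genes: set[str],
    lineage_tag: int = 0,
) -> ExpressionTable:
    """Expression after differentiation: genes targeted by the activated
    silenced-enhancer subset are scaled by ``activation_fold`` with
    lognormal noise; every other gene is jittered around no change."""
    rng = config.rng(_T_DIFF, lineage_tag)
    values: dict[str, float] = {}
    for g in sorted(expr_baseline.values):
        base = expr_baseline.values[g]
        noise = rng.lognormal(-config.expr_noise_sigma**2 / 2,
                              config.expr_noise_sigma)
        if math.isnan(base):
            values[g] = math.nan
            continue
        fold = config.activation_fold if g in activated_target_genes else 1.0
        values[g] = base * fold * noise
    return ExpressionTable(
        values=values,
        library_size_plus=expr_baseline.library_size_plus,
        library_size_minus=expr_baseline.library_size_minus,
    )


def simulate_change_experiment(
    rng: np.random.Generator,
    n_targets: int = 50,
    n_background: int = 500,
    target_log2_shift: float = 0.0,
    noise_sigma_log2: float = 0.72,
    pseudocount: float = 1.0,
) -> tuple[set[str], ExpressionTable, ExpressionTable]:
    """Paired expression tables for calibrating the expression-change test.

    Every gene's log2 fold change (on the pseudocounted scale) is Gaussian
    noise; target genes additionally receive ``target_log2_shift``. With a
    zero shift targets and background are exchangeable, giving a null
    dataset; a positive shift gives a power dataset.
    """
    total = n_targets + n_background
    ids = [f"g_{i:04d}" for i in range(total)]
    base = rng.lognormal(math.log(10.0), 1.0, size=total)
    change = rng.normal(0.0, noise_sigma_log2, size=total)
    change[:n_targets] += target_log2_shift
    after = np.maximum((base + pseudocount) * np.exp2(change) - pseudocount, 0.0)
    expr_a = ExpressionTable(values=dict(zip(ids, base.tolist())))
    expr_b = ExpressionTable(values=dict(zip(ids, after.tolist())))
    return set(ids[:n_targets]), expr_a, expr_b


def _planted_expression(
    genes: Sequence[GeneModel],
    gene_rates: Mapping[str, float],
    tracks: Mapping[str, CoverageTrack],
    config: SimulationConfig,
) -> ExpressionTable:
    """Ground-truth RPKM implied by the planted gene-body rates and the
    realized library sizes."""
    lib = {"+": tracks["GROseq_plus"].total_mapped_reads,
           "-": tracks["GROseq_minus"].total_mapped_reads}
    values: dict[str, float] = {}
    for g in genes:
        w = derive_windows(g).quant_window
        if w is None:
            values[g.gene_id] = math.nan
            continue
        rate = gene_rates[g.gene_id]  # reads per bin
        rpkm = rate * (1000.0 / config.bin_size) / (lib[g.strand] / 1e6)
        values[g.gene_id] = rpkm
    return ExpressionTable(
        values=values,
        library_size_plus=lib["+"],
        library_size_minus=lib["-"],
    )


@dataclass
class SimulatedStudy:
    """Everything one seed generates, with ground truth attached."""

    config: SimulationConfig
    genes: list[GeneModel]
    gene_rates: dict[str, float]
    tfbs: list[GenomicInterval]
    labels: list[str]
    tracks: dict[str, CoverageTrack]              # baseline (ESC) state
    tracks_npc: dict[str, CoverageTrack]          # lineage-activated marks
    activation_calls: dict[str, np.ndarray]
    target_genes: dict[str, str]                  # silenced region -> gene
    interactions_esc: list[InteractionPair]
    interactions_npc: list[InteractionPair]
    truth_targets_esc: dict[str, set[str]]
    truth_targets_npc: dict[str, set[str]]
    expr_esc: ExpressionTable
    expr_npc: ExpressionTable

    def distal_mask(self) -> np.ndarray:
        specs = {a.name: a for a in self.config.archetypes}
        return np.array([not specs[l].proximal for l in self.labels])


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genome, tracks, interactions in two cell
    states, activation calls and post-differentiation expression."""
    genes, tfbs, labels = simulate_genome(config)
    gene_rates = simulate_gene_rates(genes, config)
    tracks = simulate_tracks(genes, tfbs, labels, config, gene_rates)
    calls = simulate_activation(tfbs, labels, genes, config)
    target_genes = assign_target_genes(tfbs, labels, genes, gene_rates, config)

    first_lineage = next(iter(config.lineage_fractions), None)
    npc_regions = (
        [r.name for r, on in zip(tfbs, calls[first_lineage]) if on]
        if first_lineage
        else []
    )
    inter_esc, truth_esc = simulate_interactions(
        tfbs, labels, genes, config, target_genes)
    inter_npc, truth_npc = simulate_interactions(
        tfbs, labels, genes, config, target_genes,
        extra_wired=[n for n in npc_regions if n in target_genes])

    # lineage-activated H3K4me1/2 tracks for the first lineage
    centers = {r.name: r.center for r in tfbs}
    extra = {
        "H3K4me1": [(centers[n], config.activated_k4me1_amp) for n in npc_regions],
        "H3K4me2": [(centers[n], config.activated_k4me2_amp) for n in npc_regions],
    }
    npc_all = simulate_tracks(genes, tfbs, labels, config, gene_rates,
                              extra_bumps=extra, state_tag=1)
    tracks_npc = {m: npc_all[m] for m in ("H3K4me1", "H3K4me2")}

    expr_esc = _planted_expression(genes, gene_rates, tracks, config)
    gained = set(truth_npc) - set(truth_esc)
    activated_targets = {g for r in gained for g in truth_npc[r]}
    expr_npc = simulate_differentiation(expr_esc, config, activated_targets)

    return SimulatedStudy(
        config=config,
        genes=genes,
        gene_rates=gene_rates,
        tfbs=tfbs,
        labels=labels,
        tracks=tracks,
        tracks_npc=tracks_npc,
        activation_calls=calls,
        target_genes=target_genes,
        interactions_esc=inter_esc,
        interactions_npc=inter_npc,
        truth_targets_esc=truth_esc,
        truth_targets_npc=truth_npc,
        expr_esc=expr_esc,
        expr_npc=expr_npc,
    )


def write_fixtures(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the study to standard text formats (BED, bedGraph, gene table,
    BEDPE, expression TSVs) plus ground-truth sidecar TSVs. Deterministic:
    same study object -> byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.tsv"
    write_genes(study.genes, paths["genes"])
    paths["tfbs"] = outdir / "tfbs.bed"
    write_bed(study.tfbs, paths["tfbs"])

    paths["truth_labels"] = outdir / "truth_labels.tsv"
    with open(paths["truth_labels"], "w") as fh:
        fh.write("region\tarchetype\n")
        for r, l in zip(study.tfbs, study.labels):
            fh.write(f"{r.name}\t{l}\n")

    for mark, track in study.tracks.items():
        p = outdir / f"{mark}.bedgraph"
        write_bedgraph(track, p)
        paths[f"track:{mark}"] = p
    for mark, track in study.tracks_npc.items():
        p = outdir / f"{mark}_NPC.bedgraph"
        write_bedgraph(track, p)
        paths[f"track_npc:{mark}"] = p

    paths["libsizes"] = outdir / "library_sizes.tsv"
    with open(paths["libsizes"], "w") as fh:
        fh.write("track\ttotal_mapped_reads\n")
        for mark in sorted(study.tracks):
            fh.write(f"{mark}\t{study.tracks[mark].total_mapped_reads}\n")
        for mark in sorted(study.tracks_npc):
            fh.write(f"{mark}_NPC\t{study.tracks_npc[mark].total_mapped_reads}\n")

    paths["interactions_esc"] = outdir / "interactions_esc.bedpe"
    write_interactions(study.interactions_esc, paths["interactions_esc"])
    paths["interactions_npc"] = outdir / "interactions_npc.bedpe"
    write_interactions(study.interactions_npc, paths["interactions_npc"])

    for state, truth in (("esc", study.truth_targets_esc),
                         ("npc", study.truth_targets_npc)):
        p = outdir / f"truth_targets_{state}.tsv"
        with open(p, "w") as fh:
            fh.write("region\tgene_id\n")
            for rname in sorted(truth):
                for g in sorted(truth[rname]):
                    fh.write(f"{rname}\t{g}\n")
        paths[f"truth_targets_{state}"] = p

    paths["expression_esc"] = outdir / "expression_esc.tsv"
    study.expr_esc.write_tsv(paths["expression_esc"])
    paths["expression_npc"] = outdir / "expression_npc.tsv"
    study.expr_npc.write_tsv(paths["expression_npc"])

    paths["activation_calls"] = outdir / "activation_calls.tsv"
    with open(paths["activation_calls"], "w") as fh:
        lineages = list(study.activation_calls)
        fh.write("region\t" + "\t".join(lineages) + "\n")
        for i, r in enumerate(study.tfbs):
            row = "\t".join(
                "1" if study.activation_calls[l][i] else "0" for l in lineages
            )
            fh.write(f"{r.name}\t{row}\n")
    return paths
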