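"""GRO-seq transcription quantification and sorted trend analysis.

Gene windows follow the run-on-sequencing conventions: promoter = -1 kb to
+500 bp around the TSS, 3' end = +/-500 bp around the TTS, gene body =
TSS+500 to TTS-500, and the *quantification* window TSS+500 to TTS — the
first 500 bp are excluded so promoter-proximal PolII pausing does not
inflate gene-body RPKM. Nascent transcription is strand-specific, so reads
are counted on the gene's sense strand only.

The sorted trend operators reproduce the heat-map companion curves: regions
are sorted by one quantity (e.g. 5hmC core signal, descending) and a second
quantity (e.g. nascent transcription of the nearest gene) is smoothed with a
sliding window of 100 regions along that ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import CoverageTrack, GeneModel, GenomicInterval

__all__ = [
    "GeneWindows",
    "ExpressionTable",
    "derive_windows",
    "gene_rpkm",
    "expression_table",
    "region_nascent_signal",
    "sorted_moving_average",
    "sorted_correlation",
]

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500
PAUSE_EXCLUSION = 500
THREE_PRIME_HALFWIDTH = 500


@dataclass
class GeneWindows:
    """Promoter / gene-body / 3'-end / quantification windows for one gene.

    ``gene_body`` and ``quant_window`` are None (flagged empty) when the
    gene is too short for the windows to have positive width.
    """

    gene_id: str
    promoter: GenomicInterval
    three_prime: GenomicInterval
    gene_body: GenomicInterval | None
    quant_window: GenomicInterval | None

    @property
    def gene_body_empty(self) -> bool:
        return self.gene_body is None

    @property
    def quant_empty(self) -> bool:
        return self.quant_window is None


def _interval_or_none(chrom: str, start: int, end: int, strand: str,
                      name: str) -> GenomicInterval | None:
    start = max(0, start)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end, strand, name)


def derive_windows(gene: GeneModel) -> GeneWindows:
    """Derive the standard windows, mirrored on the minus strand and
    clipped at coordinate 0."""
    g = gene
    if g.strand == "+":
        promoter = (g.tss - PROMOTER_UPSTREAM, g.tss + PROMOTER_DOWNSTREAM)
        body = (g.tss + PAUSE_EXCLUSION, g.tts - PAUSE_EXCLUSION)
        three = (g.tts - THREE_PRIME_HALFWIDTH, g.tts + THREE_PRIME_HALFWIDTH)
        quant = (g.tss + PAUSE_EXCLUSION, g.tts)
    else:
        promoter = (g.tss - PROMOTER_DOWNSTREAM, g.tss + PROMOTER_UPSTREAM)
        body = (g.tts + PAUSE_EXCLUSION, g.tss - PAUSE_EXCLUSION)
        three = (g.tts - THREE_PRIME_HALFWIDTH, g.tts + THREE_PRIME_HALFWIDTH)
        quant = (g.tts, g.tss - PAUSE_EXCLUSION)
    mk = lambda se, nm: _interval_or_none(g.chrom, se[0], se[1], g.strand,
                                          f"{g.gene_id}:{nm}")
    prom = mk(promoter, "promoter")
    thr = mk(three, "three_prime")
    if prom is None or thr is None:
        raise ValueError(f"gene {g.gene_id}: degenerate promoter/3' window")
    return GeneWindows(
        gene_id=g.gene_id,
        promoter=prom,
        three_prime=thr,
        gene_body=mk(body, "gene_body"),
        quant_window=mk(quant, "quant"),
    )


def gene_rpkm(
    gene: GeneModel,
    gro_plus: CoverageTrack,
    gro_minus: CoverageTrack,
) -> float:
    """Nascent-transcription RPKM for one gene.

    Reads are counted on the sense strand only, within the quantification
    window (TSS+500 to TTS). Tracks must be raw counts with known library
    sizes. Returns NaN for genes whose quantification window is empty.
    """
    if gro_plus.normalized or gro_minus.normalized:
        raise ValueError("gene_rpkm requires raw (unnormalized) count tracks")
    windows = derive_windows(gene)
    if windows.quant_window is None:
        return math.nan
    sense = gro_plus if gene.strand == "+" else gro_minus
    w = windows.quant_window
    count = sense.window_read_count(w.chrom, w.start, w.end)
    kb = (w.end - w.start) / 1000.0
    millions = sense.total_mapped_reads / 1e6
    return count / kb / millions


@dataclass
class ExpressionTable:
    """gene_id -> nascent RPKM (NaN marks genes with no quantifiable window)."""

    values: dict[str, float]
    library_size_plus: int = 0
    library_size_minus: int = 0

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def valid_genes(self) -> set[str]:
        return {g for g, v in self.values.items() if not math.isnan(v)}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\trpkm\n")
            for g in sorted(self.values):
                v = self.values[g]
                fh.write(f"{g}\t{'NA' if math.isnan(v) else format(v, '.6g')}\n")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("gene_id", "#")):
                    continue
                g, v = line.split("\t")[:2]
                values[g] = math.nan if v == "NA" else float(v)
        return cls(values=values)


def expression_table(
    genes: Sequence[GeneModel],
    gro_plus: CoverageTrack,
    gro_minus: CoverageTrack,
) -> ExpressionTable:
    """RPKM for every gene (see :func:`gene_rpkm`)."""
    return ExpressionTable(
        values={g.gene_id: gene_rpkm(g, gro_plus, gro_minus) for g in genes},
        library_size_plus=gro_plus.total_mapped_reads,
        library_size_minus=gro_minus.total_mapped_reads,
    )


def region_nascent_signal(
    regions: Sequence[GenomicInterval],
    gro_plus: CoverageTrack,
    gro_minus: CoverageTrack,
    flank: int = 2000,
) -> np.ndarray:
    """Total nascent signal (plus + minus strand mean RPKM) in +/-flank of
    each region center — the eRNA-level readout; eRNAs are bidirectional so
    both strands contribute."""
    if not (gro_plus.normalized and gro_minus.normalized):
        raise ValueError("region_nascent_signal requires normalized tracks")
    out = np.zeros(len(regions))
    for i, r in enumerate(regions):
        c = r.center
        for track in (gro_plus, gro_minus):
            if r.chrom in track.chrom_vectors:
                out[i] += track.window_mean(r.chrom, c - flank, c + flank)
    return out


def _descending_order(
    sort_key: np.ndarray, names: Sequence[str] | None
) -> np.ndarray:
    if names is None:
        tie = np.arange(len(sort_key))
    else:
        tie = np.asarray(names)
        if len(tie) != len(sort_key):
            raise ValueError("names length must match sort_key")
    # lexsort: last key is primary; -key ascending == key descending
    return np.lexsort((tie, -np.asarray(sort_key, dtype=float)))


def sorted_moving_average(
    sort_key,
    companion,
    window: int = 100,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Sliding mean of ``companion`` along the descending ``sort_key`` order.

    Regions are sorted by sort_key (descending; ties broken by region name,
    else by input position) and output i is the mean of companion over
    sorted positions [i, i+window). Output length is n - window + 1.
    """
    key = np.asarray(sort_key, dtype=float)
    comp = np.asarray(companion, dtype=float)
    if key.shape != comp.shape:
        raise ValueError("sort_key and companion must have equal length")
    n = key.size
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}]")
    order = _descending_order(key, names)
    c = comp[order]
    csum = np.concatenate(([0.0], np.cumsum(c)))
    return (csum[window:] - csum[:-window]) / window


def sorted_correlation(
    sort_key,
    companion,
    window: int = 100,
    names: Sequence[str] | None = None,
) -> float:
    """Spearman correlation between the sliding means of the sorted key and
    of the companion, along the descending-key ordering.

    Returns NaN when either smoothed series has zero variance.
    """
    key = np.asarray(sort_key, dtype=float)
    comp = np.asarray(companion, dtype=float)
    if key.shape != comp.shape:
        raise ValueError("sort_key and companion must have equal length")
    n = key.size
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}]")
    order = _descending_order(key, names)
    csum_k = np.concatenate(([0.0], np.cumsum(key[order])))
    ma_key = (csum_k[window:] - csum_k[:-window]) / window
    ma_comp = sorted_moving_average(key, comp, window, names)
    if np.ptp(ma_key) == 0 or np.ptp(ma_comp) == 0:
        return math.nan
    rho, _ = stats.spearmanr(ma_key, ma_comp)
    return float(rho)
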