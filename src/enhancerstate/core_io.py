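"""Domain types and readers/writers for the standard genomic text formats.

Everything downstream works on four in-memory types:

* :class:`GenomicInterval` — a 0-based half-open span (TFBSs, DHSs, anchors,
  windows).
* :class:`GeneModel` — a gene reduced to chrom/strand/TSS/TTS, from which
  promoter, gene-body and 3'-end windows are derived.
* :class:`CoverageTrack` — per-chromosome binned signal (raw read counts per
  bin, or RPKM after normalization) with the library size attached.
* :class:`InteractionPair` — one ChIA-PET interaction: two anchors in
  canonical (sorted) order plus a paired-end-tag support count.

Coordinates are BED-convention 0-based half-open everywhere; region
"position" for distances and profiles is the interval midpoint. Chromosome
names are matched by exact string equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "CoverageTrack",
    "InteractionPair",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_interactions",
    "write_interactions",
    "read_genes",
    "write_genes",
    "nearest_tss_distance",
]

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when a text record cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional strand/label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        """Midpoint, floor((start+end)/2)."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene as chrom/strand/TSS/TTS.

    TSS and TTS are oriented: on ``+`` the TSS is upstream (tss < tts), on
    ``-`` it is downstream (tss > tts).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tts")

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Binned genome-wide signal with library size.

    ``chrom_vectors`` maps chromosome name to a float vector of per-bin
    values. Raw tracks store read counts per bin; after
    :func:`~enhancerstate.signal_matrix.rpkm_normalize` the values are RPKM
    and ``normalized`` is True. Queries outside the stored vectors return 0
    (implicit zero padding), so window statistics are insensitive to
    chromosome-boundary handling.
    """

    bin_size: int
    chrom_vectors: dict[str, np.ndarray]
    total_mapped_reads: int
    normalized: bool = False
    _prefix_cache: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be > 0")
        for chrom, vec in self.chrom_vectors.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: chrom vector must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: coverage values must be >= 0")
            self.chrom_vectors[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_vectors)

    def _prefix(self, chrom: str) -> np.ndarray:
        pre = self._prefix_cache.get(chrom)
        if pre is None:
            vec = self.chrom_vectors[chrom]
            pre = np.concatenate(([0.0], np.cumsum(vec)))
            self._prefix_cache[chrom] = pre
        return pre

    def _cum_at(self, chrom: str, pos) -> np.ndarray:
        """Integral of the per-base step function (bin value at each base)
        from 0 to ``pos``, divided by bin_size kept implicit: returns
        sum over bins of value * overlap_bp."""
        vec = self.chrom_vectors[chrom]
        b = self.bin_size
        n = len(vec)
        x = np.clip(np.asarray(pos, dtype=float), 0, n * b)
        k = np.minimum((x // b).astype(int), n - 1) if n else np.zeros_like(x, int)
        if n == 0:
            return np.zeros_like(x)
        pre = self._prefix(chrom)
        return pre[k] * b + vec[k] * (x - k * b)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """sum_bins value_b * overlap([start,end), bin_b) in base pairs."""
        if chrom not in self.chrom_vectors:
            return 0.0
        lo, hi = self._cum_at(chrom, [start, end])
        return float(hi - lo)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value (i.e. mean bin value weighted by overlap)
        over [start, end); out-of-range bases count as 0."""
        if end <= start:
            raise ValueError("window must have positive width")
        return self.integral(chrom, start, end) / (end - start)

    def window_read_count(self, chrom: str, start: int, end: int) -> float:
        """Reads falling in [start, end) for a raw count track; bins that
        partially overlap contribute fractionally."""
        return self.integral(chrom, start, end) / self.bin_size

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            bin_size=self.bin_size,
            chrom_vectors={c: v.copy() for c, v in self.chrom_vectors.items()},
            total_mapped_reads=self.total_mapped_reads,
            normalized=self.normalized,
        )


def _canonical_anchor_order(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[GenomicInterval, GenomicInterval]:
    if (a.chrom, a.start, a.end) <= (b.chrom, b.start, b.end):
        return a, b
    return b, a


@dataclass(frozen=True)
class InteractionPair:
    """One chromatin interaction: two anchors and a PET support count.

    Anchors are stored in canonical order (sorted by chrom, start, end), so
    pairs constructed from either anchor order compare equal.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    support: int = 1

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        a, b = _canonical_anchor_order(self.anchor1, self.anchor2)
        object.__setattr__(self, "anchor1", a)
        object.__setattr__(self, "anchor2", b)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what}: {text!r}") from None


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals in file order.

    Track/browser/comment lines are skipped; trailing columns tolerated.
    Malformed coordinates raise :class:`ParseError` naming the line.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"line {lineno}: expected >= 3 tab-separated columns")
        start = _parse_int(f[1], "start", lineno)
        end = _parse_int(f[2], "end", lineno)
        name = f[3] if len(f) > 3 else ""
        score: float | None = None
        if len(f) > 4 and f[4] not in (".", ""):
            try:
                score = float(f[4])
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric score {f[4]!r}") from None
        strand = f[5] if len(f) > 5 else "."
        try:
            out.append(GenomicInterval(f[0], start, end, strand, name, score))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return out


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    return f"{score:g}"


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write BED6, one line per interval, in the given order."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                f"\t{_fmt_score(iv.score)}\t{iv.strand}\n"
            )


def read_bedgraph(path, bin_size: int, total_mapped_reads: int) -> CoverageTrack:
    """Rasterize a bedGraph to a binned :class:`CoverageTrack`.

    Each record's value applies uniformly over its span; a bin's value is
    the length-weighted mean of the records covering it, so total mass
    (sum of bin value x bin width) equals sum of record value x record
    length. Overlapping records on a chromosome are an error.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    records: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 4:
            raise ParseError(f"line {lineno}: expected 4 bedGraph columns")
        start = _parse_int(f[1], "start", lineno)
        end = _parse_int(f[2], "end", lineno)
        if not 0 <= start < end:
            raise ParseError(f"line {lineno}: require 0 <= start < end")
        try:
            value = float(f[3])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric value {f[3]!r}") from None
        records.setdefault(f[0], []).append((start, end, value))

    vectors: dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        for s, e, _ in recs:
            if s < prev_end:
                raise ParseError(f"overlapping bedGraph records on {chrom} at {s}")
            prev_end = e
        n_bins = int(np.ceil(recs[-1][1] / bin_size))
        vec = np.zeros(n_bins)
        for s, e, v in recs:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                vec[b0] += v * (e - s)
            else:
                vec[b0] += v * ((b0 + 1) * bin_size - s)
                vec[b1] += v * (e - b1 * bin_size)
                if b1 > b0 + 1:
                    vec[b0 + 1 : b1] += v * bin_size
        vectors[chrom] = vec / bin_size
    return CoverageTrack(
        bin_size=bin_size,
        chrom_vectors=vectors,
        total_mapped_reads=total_mapped_reads,
        normalized=False,
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write one record per nonzero bin, chromosomes in sorted order."""
    b = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vec = track.chrom_vectors[chrom]
            for j in np.flatnonzero(vec):
                fh.write(f"{chrom}\t{j * b}\t{(j + 1) * b}\t{vec[j]:g}\n")


def read_interactions(path) -> list[InteractionPair]:
    """Read BEDPE interactions; support from column 8 (score) when present,
    else 1. Anchor order is canonicalized."""
    out: list[InteractionPair] = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"line {lineno}: expected >= 6 BEDPE columns")
        try:
            a1 = GenomicInterval(f[0], _parse_int(f[1], "start1", lineno),
                                 _parse_int(f[2], "end1", lineno))
            a2 = GenomicInterval(f[3], _parse_int(f[4], "start2", lineno),
                                 _parse_int(f[5], "end2", lineno))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        support = 1
        if len(f) > 7 and f[7] not in (".", ""):
            support = max(1, int(float(f[7])))
        out.append(InteractionPair(a1, a2, support))
    return out


def write_interactions(pairs: Sequence[InteractionPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.anchor1, p.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t.\t{p.support}\n"
            )


def read_genes(path) -> list[GeneModel]:
    """Read a gene table: tab-separated gene_id, chrom, strand, tss, tts.

    A header line starting with 'gene_id' is skipped. TSS/TTS are 0-based
    and strand-oriented (tss > tts on the minus strand).
    """
    out: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        if line.startswith("gene_id"):
            continue
        f = line.split("\t")
        if len(f) < 5:
            raise ParseError(f"line {lineno}: expected 5 gene-table columns")
        try:
            out.append(
                GeneModel(f[0], f[1], f[2], _parse_int(f[3], "tss", lineno),
                          _parse_int(f[4], "tts", lineno))
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return out


def write_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttts\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}\n")


def nearest_tss_distance(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[int, str]:
    """Distance from the region midpoint to the nearest annotated TSS.

    Returns ``(distance_bp, gene_id)``; ties go to the lexicographically
    smaller gene_id. Genes on other chromosomes are ignored unless no gene
    shares the region's chromosome, in which case all genes are considered
    infinitely far and an error is raised.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    c = region.center
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != region.chrom:
            continue
        d = abs(c - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None:
        raise ValueError(f"no gene on chromosome {region.chrom}")
    return best


def warn_unmatched_chroms(regions: Sequence[GenomicInterval],
                          track: CoverageTrack) -> set[str]:
    """Warn (once) about region chromosomes absent from a track."""
    missing = {r.chrom for r in regions} - set(track.chrom_vectors)
    if missing:
        warnings.warn(
            "regions on chromosomes absent from track: "
            + ", ".join(sorted(missing)),
            stacklevel=2,
        )
    return missing
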