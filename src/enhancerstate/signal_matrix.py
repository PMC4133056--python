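"""RPKM normalization and region x bin signal matrices around region centers.

A :class:`SignalMatrix` holds, for one mark, the mean RPKM in fixed-width
bins across a symmetric window (default +/-2 kb, 100-bp bins) centered on
each region's midpoint. Stacked across marks (see
:class:`~enhancerstate.cluster_model.FeatureMatrix`) these matrices are the
feature space for chromatin-state clustering; averaged over a region subset
they give the familiar meta-profile plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import CoverageTrack, GenomicInterval

__all__ = [
    "SignalMatrix",
    "rpkm_normalize",
    "compute_matrix",
    "average_profile",
    "enrichment_call",
    "write_matrix_tsv",
]


@dataclass
class SignalMatrix:
    """regions x bins signal for one mark around region centers."""

    mark_name: str
    regions: list[GenomicInterval]
    flank: int
    bin_size: int
    values: np.ndarray
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.flank % self.bin_size != 0:
            raise ValueError("flank must be divisible by bin_size")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.regions), 2 * self.flank // self.bin_size)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != expected {expected}"
            )
        if np.any(self.values < 0):
            raise ValueError("signal values must be >= 0")
        if self.cap is not None and self.values.size and self.values.max() > self.cap:
            raise ValueError("values exceed declared cap")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    def bin_offsets(self) -> np.ndarray:
        """Start offset of each column relative to the region center."""
        return -self.flank + np.arange(self.n_bins) * self.bin_size

    def core_slice(self, core_halfwidth: int) -> slice:
        """Columns fully inside +/-core_halfwidth of the center."""
        if core_halfwidth > self.flank:
            raise ValueError("core_halfwidth must be <= flank")
        j0 = (self.flank - core_halfwidth) // self.bin_size
        j1 = (self.flank + core_halfwidth) // self.bin_size
        return slice(j0, j1)

    def core_means(self, core_halfwidth: int) -> np.ndarray:
        """Per-region mean signal within +/-core_halfwidth of the center."""
        return self.values[:, self.core_slice(core_halfwidth)].mean(axis=1)


def rpkm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Convert a raw count track to RPKM.

    Each bin value v (reads in the bin) becomes
    ``v / (bin_size/1000) / (total_mapped_reads/1e6)``. Normalizing an
    already-normalized track is an error (double normalization).
    """
    if track.normalized:
        raise ValueError("track is already RPKM-normalized")
    factor = (track.bin_size / 1000.0) * (track.total_mapped_reads / 1e6)
    return CoverageTrack(
        bin_size=track.bin_size,
        chrom_vectors={c: v / factor for c, v in track.chrom_vectors.items()},
        total_mapped_reads=track.total_mapped_reads,
        normalized=True,
    )


def compute_matrix(
    regions: Sequence[GenomicInterval],
    track: CoverageTrack,
    flank: int = 2000,
    bin_size: int = 100,
    cap: float | None = None,
    flip_negative_strand: bool = False,
) -> SignalMatrix:
    """Mean RPKM in ``bin_size`` bins across ``+/-flank`` of each region center.

    Windows overhanging chromosome ends are zero-padded. Regions on
    chromosomes absent from the track get all-zero rows (with a warning).
    If ``cap`` is given, values are clipped at it — this emulates the
    saturated heat-map scale conventionally used for clustering inputs and
    bounds outlier influence on correlation distances. With
    ``flip_negative_strand``, rows for minus-strand regions are reversed so
    all profiles read 5'->3'.
    """
    if not track.normalized:
        raise ValueError("compute_matrix requires an RPKM-normalized track")
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_cols = 2 * flank // bin_size
    missing = {r.chrom for r in regions} - set(track.chrom_vectors)
    if missing:
        warnings.warn(
            "regions on chromosomes absent from track "
            f"({track and ', '.join(sorted(missing))}); their rows are zero",
            stacklevel=2,
        )
    values = np.zeros((len(regions), n_cols))
    edge_offsets = -flank + np.arange(n_cols + 1) * bin_size
    for i, r in enumerate(regions):
        if r.chrom in missing:
            continue
        edges = r.center + edge_offsets
        cum = track._cum_at(r.chrom, edges)
        row = (cum[1:] - cum[:-1]) / bin_size
        if flip_negative_strand and r.strand == "-":
            row = row[::-1]
        values[i] = row
    values = np.maximum(values, 0.0)
    if cap is not None:
        values = np.minimum(values, cap)
    return SignalMatrix(
        mark_name=getattr(track, "mark_name", "") or "",
        regions=list(regions),
        flank=flank,
        bin_size=bin_size,
        values=values,
        cap=cap,
    )


def average_profile(
    matrix: SignalMatrix, subset: Sequence[int] | None = None
) -> np.ndarray:
    """Column-wise mean profile over all rows or a row subset."""
    if subset is None:
        rows = matrix.values
    else:
        idx = np.asarray(list(subset), dtype=int)
        if idx.size == 0:
            raise ValueError("subset must be non-empty")
        if idx.min() < 0 or idx.max() >= matrix.values.shape[0]:
            raise IndexError("subset indices out of range")
        rows = matrix.values[idx]
    if rows.shape[0] == 0:
        raise ValueError("matrix has no rows")
    return rows.mean(axis=0)


def enrichment_call(
    matrix: SignalMatrix,
    region_index: int,
    core_halfwidth: int,
    background_level: float,
    fold_threshold: float,
) -> bool:
    """True iff the mean signal within +/-core_halfwidth of the center is at
    least ``fold_threshold`` times the background level."""
    if background_level <= 0:
        raise ValueError("background_level must be > 0")
    core = matrix.values[region_index, matrix.core_slice(core_halfwidth)]
    return bool(core.mean() >= fold_threshold * background_level)


def write_matrix_tsv(matrix: SignalMatrix, path) -> None:
    """Write a matrix as TSV: header of bin start offsets, rows keyed by
    region name (falling back to coordinates)."""
    offsets = matrix.bin_offsets()
    with open(path, "w") as fh:
        fh.write("region\t" + "\t".join(str(o) for o in offsets) + "\n")
        for r, row in zip(matrix.regions, matrix.values):
            key = r.name or f"{r.chrom}:{r.start}-{r.end}"
            fh.write(key + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
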