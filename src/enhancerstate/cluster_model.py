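"""K-means clustering of TFBS chromatin profiles and signature labeling.

Regions are clustered on column-concatenated multi-mark signal matrices
using Lloyd iteration with the correlation-magnitude distance
``d(x, y) = 1 - |pearson_r(x, y)|`` (the "Pearson correlation, absolute
distance" metric of classic microarray clustering tools) and
arithmetic-mean centroid updates. Clusters are then characterized by their
mean core signal per mark — including marks that were *not* clustering
features — and labeled by explicit enrichment/depletion rules. The label of
interest is *silenced-enhancer*: 5hmC-enriched but depleted of H3K4me1,
H3K27ac and nascent transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval
from .signal_matrix import SignalMatrix

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "ClusterSignature",
    "pearson_abs_distance",
    "kmeans_cluster",
    "characterize_clusters",
    "silenced_enhancer_regions",
    "CLUSTERING_MARKS",
    "REQUIRED_LABEL_MARKS",
]

#: Marks used as clustering features; every other mark supplied to
#: :func:`characterize_clusters` is characterization-only.
CLUSTERING_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K27me3", "5hmC")

#: Marks the labeling rules need.
REQUIRED_LABEL_MARKS = ("5hmC", "H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "GROseq")

LABELS = ("promoter-like", "active-enhancer", "silenced-enhancer", "polycomb", "other")


@dataclass
class FeatureMatrix:
    """Column-concatenation of per-mark signal matrices sharing row order."""

    regions: list[GenomicInterval]
    mark_blocks: list[tuple[str, SignalMatrix]]
    matrix: np.ndarray

    @classmethod
    def from_matrices(cls, matrices: Sequence[SignalMatrix]) -> "FeatureMatrix":
        if not matrices:
            raise ValueError("need at least one signal matrix")
        first = matrices[0]
        for m in matrices[1:]:
            if len(m.regions) != len(first.regions) or any(
                a is not b and (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end)
                for a, b in zip(m.regions, first.regions)
            ):
                raise ValueError("all signal matrices must share the region list")
        return cls(
            regions=list(first.regions),
            mark_blocks=[(m.mark_name, m) for m in matrices],
            matrix=np.hstack([m.values for m in matrices]),
        )

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ClusterModel:
    """Result of one K-means run: assignments, centroids and diagnostics."""

    K: int
    regions: list[GenomicInterval]
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int
    n_restarts: int
    n_iter: int = 0
    inertia_history: list[float] = field(default_factory=list)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float(xc @ yc / (sx * sy))


def pearson_abs_distance(x, y) -> float:
    """``1 - |r(x, y)|`` with deterministic handling of flat profiles.

    A zero-variance vector has no defined correlation; such a pair is
    maximally distant (1.0) unless both vectors are constant and equal, in
    which case they are identical profiles and the distance is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    r = _pearson_r(x, y)
    if np.isnan(r):
        x_const = np.ptp(x) == 0
        y_const = np.ptp(y) == 0
        if x_const and y_const and x[0] == y[0]:
            return 0.0
        return 1.0
    d = float(np.clip(1.0 - abs(r), 0.0, 1.0))
    return 0.0 if d < 1e-12 else d


def _row_zscores(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit L2 norm; flags and means for the
    zero-variance rows (left as zero vectors)."""
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    norms = np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    const = norms[:, 0] == 0
    Z = np.divide(Xc, norms, out=np.zeros_like(Xc), where=norms > 0)
    return Z, const, mu[:, 0]


def _distance_matrix(
    Z: np.ndarray, const: np.ndarray, mu: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Pairwise pearson_abs_distance between all rows (pre-standardized)
    and all centroids."""
    Cz, c_const, c_mu = _row_zscores(centroids)
    D = 1.0 - np.abs(Z @ Cz.T)
    # zero-variance rules
    if const.any() or c_const.any():
        bad = const[:, None] | c_const[None, :]
        D[bad] = 1.0
        equal_flat = (
            const[:, None] & c_const[None, :] & (mu[:, None] == c_mu[None, :])
        )
        D[equal_flat] = 0.0
    return np.clip(D, 0.0, 1.0)


def _dsq_init(
    X: np.ndarray,
    Z: np.ndarray,
    const: np.ndarray,
    mu: np.ndarray,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """k-means++-style seeding under the correlation-magnitude distance:
    first centroid is a random row, each further centroid is drawn with
    probability proportional to the squared distance to the nearest one
    chosen so far. Far more reliable than uniform row sampling at covering
    well-separated profile archetypes."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d_near = _distance_matrix(Z, const, mu, X[chosen])[:, 0]
    for _ in range(1, K):
        w = d_near**2
        total = w.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n), chosen)
            chosen.append(int(rng.choice(remaining)))
        else:
            chosen.append(int(rng.choice(n, p=w / total)))
        d_new = _distance_matrix(Z, const, mu, X[chosen[-1:]])[:, 0]
        d_near = np.minimum(d_near, d_new)
    return X[chosen].copy()


def kmeans_cluster(
    features: FeatureMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
    regions: Sequence[GenomicInterval] | None = None,
) -> ClusterModel:
    """Lloyd K-means under the correlation-magnitude distance.

    Centroids are seeded with distance-squared (k-means++-style) row
    sampling and updated as arithmetic means of their members; assignment
    uses
    :func:`pearson_abs_distance`. An empty cluster is re-seeded with the
    point currently farthest from its own centroid. The best of
    ``n_restarts`` runs by inertia (sum of member-to-centroid distances) is
    returned; the whole procedure is deterministic given ``seed``. The mean
    update is not guaranteed to lower a correlation-based objective, so a
    restart stops (keeping the previous state) if its inertia would rise.
    """
    if isinstance(features, FeatureMatrix):
        X = features.matrix
        region_list = features.regions
    else:
        X = np.asarray(features, dtype=float)
        region_list = list(regions) if regions is not None else []
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError(f"need at least K={K} rows, got {n}")

    Z, const, mu = _row_zscores(X)

    best: tuple[float, np.ndarray, np.ndarray, int, list[float]] | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        centroids = _dsq_init(X, Z, const, mu, K, rng)
        assign = None
        inertia = np.inf
        history: list[float] = []
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            D = _distance_matrix(Z, const, mu, centroids)
            new_assign = D.argmin(axis=1)
            # re-seed empty clusters with the worst-fit point
            for _ in range(K):
                counts = np.bincount(new_assign, minlength=K)
                empties = np.flatnonzero(counts == 0)
                if empties.size == 0:
                    break
                k = empties[0]
                worst = int(np.argmax(D[np.arange(n), new_assign]))
                centroids[k] = X[worst]
                D = _distance_matrix(Z, const, mu, centroids)
                new_assign = D.argmin(axis=1)
            new_inertia = float(D[np.arange(n), new_assign].sum())
            if new_inertia > inertia + 1e-12:
                break  # mean update degraded the objective; keep previous state
            history.append(new_inertia)
            converged = assign is not None and np.array_equal(new_assign, assign)
            assign, inertia = new_assign, new_inertia
            if converged:
                break
            for k in range(K):
                members = X[assign == k]
                if len(members):
                    centroids[k] = members.mean(axis=0)
        if best is None or inertia < best[0]:
            # final centroids = member means of the kept assignment
            final_centroids = np.array(
                [
                    X[assign == k].mean(axis=0) if (assign == k).any() else centroids[k]
                    for k in range(K)
                ]
            )
            best = (inertia, assign.copy(), final_centroids, n_iter, history)

    inertia, assign, centroids, n_iter, history = best
    return ClusterModel(
        K=K,
        regions=region_list,
        assignments=assign,
        centroids=centroids,
        inertia=inertia,
        seed=seed,
        n_restarts=n_restarts,
        n_iter=n_iter,
        inertia_history=history,
    )


@dataclass
class ClusterSignature:
    """Per-cluster chromatin signature and label."""

    cluster_id: int
    n_members: int
    core_means: dict[str, float]
    flags: dict[str, str]  # mark -> enriched | depleted | intermediate
    label: str
    silenced_score: float = 0.0


def _flag(excess: float, scale: float, enr: float, dep: float) -> str:
    if excess >= enr * scale:
        return "enriched"
    if excess <= dep * scale:
        return "depleted"
    return "intermediate"


def _edge_background(mat: SignalMatrix, n_edge_bins: int = 5) -> float:
    """Per-mark background level: median across regions of the mean signal
    in the outermost bins of the profile window, where site-specific
    enrichment has decayed to the genomic floor."""
    v = mat.values
    k = min(n_edge_bins, v.shape[1] // 2)
    edges = np.concatenate([v[:, :k], v[:, -k:]], axis=1)
    return float(np.median(edges.mean(axis=1)))


def characterize_clusters(
    model: ClusterModel,
    all_marks: Mapping[str, SignalMatrix] | Sequence[SignalMatrix],
    enriched_threshold: float = 2.0,
    depleted_threshold: float = 0.5,
    core_halfwidth: int = 1000,
) -> list[ClusterSignature]:
    """Summarize every cluster over every supplied mark and assign labels.

    For each (cluster, mark) the mean signal within +/-core_halfwidth of
    the region centers is computed over members. Flags are assigned on the
    background-subtracted scale: each mark's genomic floor is estimated
    from the outermost profile bins and subtracted from a robust cluster
    summary (the median of member core means, insensitive to the odd
    misassigned region in heavy-tailed RPKM data; the reported
    ``core_means`` remain plain means). The per-mark reference is the
    median background excess across clusters, floored at half the
    background so marks enriched in only a few clusters still get a usable
    noise scale. A mark is *enriched* in a cluster when its excess is >=
    ``enriched_threshold`` times the reference, *depleted* when <=
    ``depleted_threshold`` times it. Labels:

    * promoter-like: H3K4me3 enriched and GROseq enriched
    * active-enhancer: H3K4me1 enriched and H3K27ac enriched
    * polycomb: H3K27me3 enriched and H3K27ac depleted
    * silenced-enhancer: 5hmC enriched, H3K4me1/H3K27ac/GROseq depleted

    At most one cluster is labeled silenced-enhancer: among qualifying
    clusters the one with the highest 5hmC-to-activating-signal contrast
    wins; the others fall through to the remaining rules.
    """
    if not isinstance(all_marks, Mapping):
        all_marks = {m.mark_name: m for m in all_marks}
    missing = [m for m in REQUIRED_LABEL_MARKS if m not in all_marks]
    if missing:
        raise ValueError("missing required marks: " + ", ".join(missing))
    n = len(model.assignments)
    for name, mat in all_marks.items():
        if mat.values.shape[0] != n:
            raise ValueError(f"mark {name}: rows not aligned with cluster model")

    clusters = list(range(model.K))
    per_mark_core = {
        name: mat.core_means(core_halfwidth) for name, mat in all_marks.items()
    }
    core: dict[int, dict[str, float]] = {k: {} for k in clusters}
    robust: dict[int, dict[str, float]] = {k: {} for k in clusters}
    for name, vals in per_mark_core.items():
        for k in clusters:
            members = model.assignments == k
            core[k][name] = float(vals[members].mean()) if members.any() else 0.0
            robust[k][name] = float(np.median(vals[members])) if members.any() else 0.0
    background = {name: _edge_background(mat) for name, mat in all_marks.items()}
    excess = {
        k: {name: robust[k][name] - background[name] for name in all_marks}
        for k in clusters
    }
    scale = {
        name: max(
            float(np.median([excess[k][name] for k in clusters])),
            0.5 * background[name],
            1e-12,
        )
        for name in all_marks
    }

    flags: dict[int, dict[str, str]] = {
        k: {
            name: _flag(excess[k][name], scale[name],
                        enriched_threshold, depleted_threshold)
            for name in all_marks
        }
        for k in clusters
    }

    def silenced_ok(k: int) -> bool:
        f = flags[k]
        return (
            f["5hmC"] == "enriched"
            and f["H3K4me1"] == "depleted"
            and f["H3K27ac"] == "depleted"
            and f["GROseq"] == "depleted"
        )

    def contrast(k: int) -> float:
        act = np.mean(
            [max(excess[k][m], 0.0) for m in ("H3K4me1", "H3K27ac", "GROseq")]
        )
        return max(excess[k]["5hmC"], 0.0) / (act + 1e-9)

    candidates = [k for k in clusters if silenced_ok(k)]
    silenced = (
        max(candidates, key=lambda k: (contrast(k), -k)) if candidates else None
    )

    signatures = []
    for k in clusters:
        f = flags[k]
        if k == silenced:
            label = "silenced-enhancer"
        elif f["H3K4me3"] == "enriched" and f["GROseq"] == "enriched":
            label = "promoter-like"
        elif f["H3K4me1"] == "enriched" and f["H3K27ac"] == "enriched":
            label = "active-enhancer"
        elif f["H3K27me3"] == "enriched" and f["H3K27ac"] == "depleted":
            label = "polycomb"
        else:
            label = "other"
        signatures.append(
            ClusterSignature(
                cluster_id=k,
                n_members=int((model.assignments == k).sum()),
                core_means=core[k],
                flags=f,
                label=label,
                silenced_score=contrast(k),
            )
        )
    return signatures


def silenced_enhancer_regions(
    signatures: Sequence[ClusterSignature], model: ClusterModel
) -> list[GenomicInterval]:
    """Members of the silenced-enhancer cluster, in input region order
    (empty when no cluster qualifies)."""
    silenced = [s.cluster_id for s in signatures if s.label == "silenced-enhancer"]
    if not silenced:
        return []
    if len(silenced) > 1:  # characterize_clusters guarantees at most one
        raise ValueError("more than one silenced-enhancer cluster")
    k = silenced[0]
    return [r for r, a in zip(model.regions, model.assignments) if a == k]
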