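"""Niche discovery: UMAP embedding of neighborhood profiles, outcome-group
2D-histogram log-ratio contrasting, and Davies-Bouldin-adaptive k-means.

Workflow: the per-cell 40-value profiles of all samples are embedded into
2D (UMAP), each outcome group's cells are binned on a shared 2D grid into a
normalized histogram, and the bin-wise log10 ratio of the deceased to alive
frequencies marks embedding territory more prevalent in one group
(thresholds +0.01 / -0.01 on the log10 scale).  Cells of each group falling
in its enriched bins are clustered by k-means in the embedding plane, with
the cluster number chosen by minimizing the Davies-Bouldin index.  Clusters
are named D1..Dk / A1..Ak by descending size, and characterized by the mean
+/- SEM of their member cells' 40-value profiles and by per-phenotype
ratio profiles between clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score

from .neighborhoods import N_PHENOTYPES

DEFAULT_LOG_RATIO_THRESHOLD = 0.01


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n, 2)
    n_neighbors: int
    min_dist: float
    metric: str
    seed: int


@dataclass
class GroupHistogram:
    x_edges: np.ndarray
    y_edges: np.ndarray
    freq_deceased: np.ndarray  # (nx, ny), sums to 1
    freq_alive: np.ndarray


@dataclass
class LogRatioField:
    x_edges: np.ndarray
    y_edges: np.ndarray
    field: np.ndarray  # log10((f_D + eps) / (f_A + eps))
    epsilon: float
    threshold: float = DEFAULT_LOG_RATIO_THRESHOLD


@dataclass
class ClusterSet:
    group: str  # 'deceased' or 'alive'
    k: int
    davies_bouldin: float
    db_per_k: dict  # k -> DB index
    labels: np.ndarray  # cluster index per selected cell, 0 = largest
    names: list  # e.g. ['D1', 'D2', ...] aligned with label index
    cell_index: np.ndarray  # positions of the selected cells in the input
    mean_profiles: np.ndarray | None = None  # (k, 40)
    sem_profiles: np.ndarray | None = None
    prevalence: np.ndarray | None = None  # fraction of group cells per cluster


def embed_profiles(
    profiles: np.ndarray,
    n_neighbors: int = 30,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 0,
    zscore: bool = False,
) -> EmbeddingResult:
    """UMAP-embed an (n, 40) profile matrix into 2D, deterministically.

    ``zscore`` optionally standardizes profile columns before embedding
    (off by default; profiles are used unscaled).
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or len(X) < 10:
        raise ValueError("need a 2D matrix with >= 10 profiles")
    if np.isnan(X).any():
        raise ValueError("profiles contain NaN")
    if len(X) <= n_neighbors:
        raise ValueError(
            f"n={len(X)} rows <= n_neighbors={n_neighbors}; reduce n_neighbors"
        )
    if zscore:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value")
        coords = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=seed,
        ).fit_transform(X)
    return EmbeddingResult(
        coords=np.asarray(coords, float),
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        seed=seed,
    )


def group_histograms(
    coords: np.ndarray, groups: np.ndarray, n_bins: int = 100
) -> GroupHistogram:
    """Per-group normalized 2D histograms on a shared grid.

    The grid spans the joint extent of both groups; each group's bin
    frequencies are its counts divided by its total cell count.
    """
    coords = np.asarray(coords, float)
    groups = np.asarray(groups)
    masks = {g: groups == g for g in ("deceased", "alive")}
    for g, m in masks.items():
        if not m.any():
            raise ValueError(f"group {g!r} has no cells")
    x_edges = np.linspace(coords[:, 0].min(), coords[:, 0].max(), n_bins + 1)
    y_edges = np.linspace(coords[:, 1].min(), coords[:, 1].max(), n_bins + 1)
    freqs = {}
    for g, m in masks.items():
        h, _, _ = np.histogram2d(
            coords[m, 0], coords[m, 1], bins=(x_edges, y_edges)
        )
        freqs[g] = h / m.sum()
    return GroupHistogram(
        x_edges=x_edges,
        y_edges=y_edges,
        freq_deceased=freqs["deceased"],
        freq_alive=freqs["alive"],
    )


def log_ratio_field(
    hist: GroupHistogram,
    epsilon: float | None = None,
    threshold: float = DEFAULT_LOG_RATIO_THRESHOLD,
) -> LogRatioField:
    """Bin-wise log10((f_deceased + eps)/(f_alive + eps)).

    ``epsilon`` defaults to one count in the larger group (1 / max group
    total is unknown here, so the caller may pass it; the fallback uses the
    smallest nonzero frequency of either histogram, which is 1/total for
    the larger group when both histograms are count-normalized).
    """
    fd, fa = hist.freq_deceased, hist.freq_alive
    if fd.shape != fa.shape:
        raise ValueError("group histograms have mismatched grids")
    if epsilon is None:
        nonzero = np.concatenate([fd[fd > 0].ravel(), fa[fa > 0].ravel()])
        epsilon = float(nonzero.min()) if len(nonzero) else 1e-6
    field = np.log10((fd + epsilon) / (fa + epsilon))
    return LogRatioField(
        x_edges=hist.x_edges,
        y_edges=hist.y_edges,
        field=field,
        epsilon=epsilon,
        threshold=threshold,
    )


def _bin_of(coords, edges_x, edges_y):
    ix = np.clip(np.searchsorted(edges_x, coords[:, 0], "right") - 1, 0,
                 len(edges_x) - 2)
    iy = np.clip(np.searchsorted(edges_y, coords[:, 1], "right") - 1, 0,
                 len(edges_y) - 2)
    return ix, iy


def prevalence_cells(
    field: LogRatioField, coords: np.ndarray, groups: np.ndarray
):
    """Index arrays of the group-enriched cells.

    Deceased-prevalent cells are deceased-group cells in bins where the
    log-ratio exceeds +threshold; alive-prevalent cells are alive-group
    cells in bins below -threshold.  The two bin sets are disjoint by
    construction.
    """
    coords = np.asarray(coords, float)
    groups = np.asarray(groups)
    ix, iy = _bin_of(coords, field.x_edges, field.y_edges)
    val = field.field[ix, iy]
    dec = np.nonzero((groups == "deceased") & (val > field.threshold))[0]
    alv = np.nonzero((groups == "alive") & (val < -field.threshold))[0]
    return dec, alv


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index (mean over clusters of the worst ratio of
    summed within-cluster mean scatters to centroid separation)."""
    return float(davies_bouldin_score(points, labels))


def adaptive_kmeans(
    points: np.ndarray,
    k_range=range(2, 11),
    seed: int = 0,
    restarts: int = 10,
    group: str = "deceased",
) -> ClusterSet:
    """k-means over a k range, keeping the Davies-Bouldin-minimizing k.

    Ties in the DB index break toward smaller k.  Clusters are relabeled by
    descending size and named ``D1..`` or ``A1..`` according to ``group``.
    """
    points = np.asarray(points, float)
    ks = sorted(k_range)
    if len(points) <= max(ks):
        raise ValueError(
            f"{len(points)} points cannot support k up to {max(ks)}"
        )
    if len(np.unique(points, axis=0)) <= max(ks):
        raise ValueError("fewer distinct points than the largest k")
    db_per_k, labels_per_k = {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                    random_state=seed)
        lab = km.fit_predict(points)
        db_per_k[k] = davies_bouldin(points, lab)
        labels_per_k[k] = lab
    best_k = min(ks, key=lambda k: (db_per_k[k], k))
    labels = labels_per_k[best_k]
    # relabel by descending cluster size (stable: ties keep original order)
    sizes = np.bincount(labels, minlength=best_k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(best_k, int)
    remap[order] = np.arange(best_k)
    labels = remap[labels]
    prefix = "D" if group == "deceased" else "A"
    return ClusterSet(
        group=group,
        k=best_k,
        davies_bouldin=db_per_k[best_k],
        db_per_k=db_per_k,
        labels=labels,
        names=[f"{prefix}{i + 1}" for i in range(best_k)],
        cell_index=np.arange(len(points)),
    )


def cluster_mean_profile(labels: np.ndarray, profiles: np.ndarray):
    """Mean and SEM (sd/sqrt(n), ddof=1) of the 40-entry profiles per cluster.

    Returns ``(means, sems)`` of shape (k, 40).  A singleton cluster gets
    SEM 0 with a warning.
    """
    labels = np.asarray(labels)
    profiles = np.asarray(profiles, float)
    if len(labels) != len(profiles):
        raise ValueError("labels and profiles are misaligned")
    k = labels.max() + 1
    means = np.zeros((k, profiles.shape[1]))
    sems = np.zeros_like(means)
    for c in range(k):
        sel = profiles[labels == c]
        if len(sel) == 0:
            raise ValueError(f"cluster {c} has no cells")
        means[c] = sel.mean(axis=0)
        if len(sel) == 1:
            warnings.warn(f"cluster {c} has a single cell; SEM reported as 0")
        else:
            sems[c] = sel.std(axis=0, ddof=1) / np.sqrt(len(sel))
    return means, sems


def characterize(
    cs: ClusterSet, profiles: np.ndarray, group_total: int
) -> ClusterSet:
    """Fill mean/SEM profiles and prevalence fractions of a ClusterSet.

    ``profiles`` are the 40-value profiles of the *selected* cells (aligned
    with ``cs.labels``); ``group_total`` is the total cell count of the
    cluster's outcome group (prevalence denominator).
    """
    cs.mean_profiles, cs.sem_profiles = cluster_mean_profile(
        cs.labels, profiles
    )
    counts = np.bincount(cs.labels, minlength=cs.k)
    if group_total < counts.sum():
        raise ValueError("group total below selected cell count")
    cs.prevalence = counts / group_total
    return cs


def cluster_ratio_profile(
    numerator_mean: np.ndarray,
    denominator_mean: np.ndarray,
    floor: float = 1.0,
) -> np.ndarray:
    """Element-wise per-phenotype ratio of two mean profiles.

    ``floor`` (cells/mm^2) bounds the denominator away from zero; with
    ``floor=0`` an all-zero denominator entry raises.
    """
    num = np.asarray(numerator_mean, float)
    den = np.asarray(denominator_mean, float)
    if num.shape != den.shape:
        raise ValueError("profile shapes differ")
    if floor == 0 and np.any(den == 0):
        raise ValueError("zero denominator entry with floor=0")
    return num / np.maximum(den, floor)


def cluster_prevalence(cs: ClusterSet, group_total: int) -> np.ndarray:
    """Fraction of the group's cells captured by each cluster."""
    counts = np.bincount(cs.labels, minlength=cs.k)
    if group_total < counts.sum():
        raise ValueError("group total below selected cell count")
    return counts / group_total


def dominant_phenotype(mean_profile: np.ndarray, max_bin: int = 2,
                       n_bins: int = 5) -> int:
    """Phenotype with the largest summed mean density over the near bins.

    ``max_bin`` is exclusive; the default 2 sums the 0-25 and 25-50 μm bins.
    """
    prof = np.asarray(mean_profile, float).reshape(N_PHENOTYPES, n_bins)
    return int(np.argmax(prof[:, :max_bin].sum(axis=1)))
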