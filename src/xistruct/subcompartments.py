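"""Spatial-cluster segmentation of a chromosome into subcompartments.

Bins sharing long-range interaction profiles are grouped by k-means on the
leading eigenvectors (each weighted by its eigenvalue) of a clipped Pearson
correlation matrix of the O/E, ICE-balanced contacts.  The k clusters are
consolidated into five subcompartments (A1, A2, AB, B1, B2) by hierarchically
grouping their mutual interaction profiles and ordering the groups by mean
compartment eigenvector, A1 highest.  Cluster labels from different samples
are aligned to a reference clustering by optimal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans

from .contact_matrix import OE, RAW, ContactMatrix, ice_balance, observed_over_expected

__all__ = [
    "SpatialClustering",
    "SUBCOMPARTMENT_NAMES",
    "build_correlation_matrix",
    "cluster_spatial",
    "align_cluster_labels",
    "cluster_interaction_matrix",
    "consolidate_subcompartments",
    "inter_megadomain_fraction",
    "annotate_clusters_with_track",
]

SUBCOMPARTMENT_NAMES = ("A1", "A2", "AB", "B1", "B2")
MISSING = -1  # cluster id marker for masked bins


@dataclass
class SpatialClustering:
    """Per-bin spatial-cluster assignment (1..k; -1 = missing/masked)."""

    cluster_id: np.ndarray
    k: int
    subcompartment: np.ndarray | None = None  # object array, None at missing
    subcompartment_of_cluster: dict[int, str] | None = None

    @property
    def valid(self) -> np.ndarray:
        return self.cluster_id != MISSING

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == c)


def build_correlation_matrix(matrix: ContactMatrix) -> np.ndarray:
    """Clipped, rescaled Pearson correlation matrix of a contact matrix.

    Pipeline: observed/expected -> ICE balancing -> clip entries above the
    90th percentile -> Pearson correlation over unmasked bins -> zero the
    diagonal -> linearly rescale so the 5th/95th percentiles map to -1/+1
    (clipping outside).  Masked bins are NaN rows/columns in the result.
    """
    if matrix.state == RAW:
        matrix = observed_over_expected(matrix)[0]
        matrix = ice_balance(
            ContactMatrix(matrix.bins,
                          np.where(np.isfinite(matrix.values), matrix.values, np.nan),
                          RAW, matrix.allele)
        )
    elif matrix.state != OE:
        matrix = observed_over_expected(matrix)[0]
    keep = matrix.unmasked
    sub = matrix.values[np.ix_(keep, keep)]
    sub = np.where(np.isfinite(sub), sub, 0.0)
    p90 = np.percentile(sub, 90)
    sub = np.minimum(sub, p90)
    sd = sub.std(axis=1)
    if (sd == 0).any():
        raise ValueError("degenerate constant rows in clipped matrix")
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 0.0)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    p5, p95 = np.percentile(off, [5, 95])
    if p95 > p5:
        corr = np.clip(2 * (corr - p5) / (p95 - p5) - 1, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    n = matrix.n_bins
    full = np.full((n, n), np.nan)
    full[np.ix_(keep, keep)] = corr
    return full


def weighted_eigenvectors(corr: np.ndarray, n_eig: int) -> np.ndarray:
    """Leading eigenvectors (algebraic order, descending) scaled by eigenvalue."""
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1][:n_eig]
    return vecs[:, order] * vals[order]


def cluster_spatial(
    corr: np.ndarray,
    k: int = 12,
    n_eig: int = 12,
    restarts: int = 10,
    seed: int = 0,
) -> SpatialClustering:
    """k-means spatial clustering on eigenvalue-weighted eigenvectors.

    Features are the ``n_eig`` leading eigenvectors of the correlation matrix
    (by algebraic eigenvalue, descending), each multiplied by its eigenvalue
    with sign retained.  k-means runs ``restarts`` initializations and the
    best within-cluster sum of squares is kept.  Labels are 1..k; masked
    bins get -1.
    """
    corr = np.asarray(corr, dtype=float)
    keep = np.isfinite(corr).any(axis=1)
    n_valid = int(keep.sum())
    if k > n_valid:
        raise ValueError(f"k={k} exceeds {n_valid} unmasked bins")
    sub = corr[np.ix_(keep, keep)]
    use_eig = min(n_eig, n_valid)
    if use_eig < n_eig:
        warnings.warn(f"only {use_eig} eigenvectors available; using those")
    feats = weighted_eigenvectors(sub, use_eig)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(feats)
    labels = np.full(len(corr), MISSING, dtype=int)
    labels[keep] = km.labels_ + 1
    return SpatialClustering(cluster_id=labels, k=k)


def align_cluster_labels(
    clustering: SpatialClustering, reference: SpatialClustering
) -> SpatialClustering:
    """Relabel clusters to maximize bin overlap with a reference clustering.

    Solves the optimal bijective assignment on the k x k contingency table of
    the two labelings (Hungarian algorithm).
    """
    if clustering.k != reference.k:
        raise ValueError("clusterings have different k")
    a, b = clustering.cluster_id, reference.cluster_id
    if len(a) != len(b):
        raise ValueError("clusterings cover different bin sets")
    both = (a != MISSING) & (b != MISSING)
    k = clustering.k
    contingency = np.zeros((k, k))
    np.add.at(contingency, (a[both] - 1, b[both] - 1), 1)
    rows, cols = linear_sum_assignment(-contingency)
    mapping = {r + 1: c + 1 for r, c in zip(rows, cols)}
    new = np.array([mapping.get(x, MISSING) for x in a], dtype=int)
    return SpatialClustering(cluster_id=new, k=k)


def cluster_interaction_matrix(
    matrix: ContactMatrix, clustering: SpatialClustering
) -> np.ndarray:
    """Mean O/E interaction between every pair of spatial clusters.

    Entry (c1, c2) averages the O/E values over all bin pairs with those
    cluster labels, excluding the matrix diagonal.  Symmetric by construction.
    """
    if matrix.state != OE:
        matrix = observed_over_expected(matrix)[0]
    vals = matrix.values.copy()
    np.fill_diagonal(vals, np.nan)
    k = clustering.k
    out = np.full((k, k), np.nan)
    members = [clustering.members(c + 1) for c in range(k)]
    for c in range(k):
        if members[c].size == 0:
            raise ValueError(f"cluster {c + 1} is empty")
    for a in range(k):
        for b in range(a, k):
            block = vals[np.ix_(members[a], members[b])]
            block = block[np.isfinite(block)]
            if block.size:
                out[a, b] = out[b, a] = block.mean()
    return out


def consolidate_subcompartments(
    clustering: SpatialClustering,
    cluster_interactions: np.ndarray,
    pc1: np.ndarray,
    n_groups: int = 5,
) -> SpatialClustering:
    """Group k clusters into named subcompartments by interaction profile.

    The k rows of the cluster-interaction matrix are hierarchically clustered
    (average linkage, Euclidean distance) into ``n_groups`` groups; groups are
    ordered by descending mean PC1 of their member bins (ties broken by the
    smallest member cluster id) and named A1, A2, AB, B1, B2 in that order.
    """
    k = clustering.k
    if k < n_groups:
        raise ValueError(f"k={k} < {n_groups} subcompartments")
    profiles = np.where(np.isfinite(cluster_interactions), cluster_interactions, 0.0)
    groups = fcluster(linkage(profiles, method="average", metric="euclidean"),
                      n_groups, criterion="maxclust")
    group_stats = []
    for g in np.unique(groups):
        cluster_ids = np.flatnonzero(groups == g) + 1
        bins = np.isin(clustering.cluster_id, cluster_ids)
        vals = pc1[bins]
        vals = vals[np.isfinite(vals)]
        mean_pc1 = vals.mean() if vals.size else -np.inf
        group_stats.append((g, mean_pc1, int(cluster_ids.min())))
    # descending mean PC1; ties -> smaller lowest cluster id first
    group_stats.sort(key=lambda t: (-t[1], t[2]))
    name_of_group = {g: SUBCOMPARTMENT_NAMES[i] for i, (g, _, _) in enumerate(group_stats)}
    sub_of_cluster = {c + 1: name_of_group[groups[c]] for c in range(k)}
    sub = np.full(len(clustering.cluster_id), None, dtype=object)
    for c, name in sub_of_cluster.items():
        sub[clustering.cluster_id == c] = name
    return SpatialClustering(
        cluster_id=clustering.cluster_id, k=k, subcompartment=sub,
        subcompartment_of_cluster=sub_of_cluster,
    )


def inter_megadomain_fraction(
    matrix: ContactMatrix,
    clustering: SpatialClustering,
    split_point: int,
    min_dist: int = 8_200_000,
    top_frac: float = 0.2,
) -> dict[int, float]:
    """Per-cluster fraction of strong long-range inter-mega-domain contacts.

    Qualifying pairs have genomic distance > ``min_dist`` and lie on opposite
    sides of ``split_point``.  The strongest ``top_frac`` of qualifying pairs
    (threshold = (1 - top_frac) quantile of values; ties at the threshold are
    included) are "strong"; each cluster's fraction is strong pairs touching
    it over all qualifying pairs touching it.  Clusters with no qualifying
    pairs map to NaN.
    """
    res = matrix.resolution
    n = matrix.n_bins
    split_bin = int(matrix.bins.bin_of(split_point))
    i, j = np.triu_indices(n, k=1)
    vals = matrix.values[i, j]
    dist = (j - i).astype(np.int64) * res
    cross = (i < split_bin) & (j >= split_bin)
    ok = np.isfinite(vals) & (dist > min_dist) & cross
    if not ok.any():
        raise ValueError("no qualifying inter-mega-domain pairs")
    i, j, vals = i[ok], j[ok], vals[ok]
    thr = np.quantile(vals, 1 - top_frac)
    strong = vals >= thr
    labels = clustering.cluster_id
    out: dict[int, float] = {}
    for c in range(1, clustering.k + 1):
        touch = (labels[i] == c) | (labels[j] == c)
        total = int(touch.sum())
        out[c] = float(strong[touch].sum() / total) if total else np.nan
    return out


def _bin_track_means(
    bins, track: pd.DataFrame
) -> np.ndarray:
    """Length-weighted mean track value per bin from bedGraph-style intervals."""
    if not (track["chrom"] == bins.chrom).all():
        raise ValueError("track is on a different chromosome")
    n = bins.n_bins
    wsum = np.zeros(n)
    w = np.zeros(n)
    starts, ends = bins.starts, bins.ends
    res = bins.resolution
    for s, e, v in track[["start", "end", "value"]].itertuples(index=False):
        b0 = max(int(s) // res, 0)
        b1 = min(int(np.ceil(e / res)), n)
        for b in range(b0, b1):
            ov = min(e, ends[b]) - max(s, starts[b])
            if ov > 0:
                wsum[b] += v * ov
                w[b] += ov
    with np.errstate(invalid="ignore"):
        return np.where(w > 0, wsum / w, np.nan)


def annotate_clusters_with_track(
    clustering: SpatialClustering,
    bins,
    track: pd.DataFrame,
    by: str = "cluster",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a genomic signal track over spatial clusters.

    ``track`` is a bedGraph-like frame (chrom, start, end, value).  Each bin
    receives the length-weighted mean of overlapping intervals; bins are then
    grouped by cluster id (``by='cluster'``) or subcompartment name
    (``by='subcompartment'``).  Returns a per-group summary and a matrix of
    two-sided Wilcoxon-Mann-Whitney p-values between groups.
    """
    per_bin = _bin_track_means(bins, track)
    if by == "subcompartment":
        if clustering.subcompartment is None:
            raise ValueError("clustering has no subcompartment labels")
        group_labels = clustering.subcompartment
        groups = [g for g in SUBCOMPARTMENT_NAMES if (group_labels == g).any()]
    else:
        group_labels = clustering.cluster_id
        groups = sorted(int(c) for c in np.unique(group_labels) if c != MISSING)
    values = {
        g: per_bin[(group_labels == g) & np.isfinite(per_bin)] for g in groups
    }
    summary = pd.DataFrame(
        {
            "group": groups,
            "n_bins": [values[g].size for g in groups],
            "mean": [values[g].mean() if values[g].size else np.nan for g in groups],
            "median": [np.median(values[g]) if values[g].size else np.nan for g in groups],
        }
    )
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)
    for a in groups:
        for b in groups:
            if a == b or not (values[a].size and values[b].size):
                continue
            if np.ptp(np.concatenate([values[a], values[b]])) == 0:
                pvals.loc[a, b] = 1.0  # identical constant samples
            else:
                pvals.loc[a, b] = mannwhitneyu(values[a], values[b],
                                               alternative="two-sided").pvalue
    return summary, pvals
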