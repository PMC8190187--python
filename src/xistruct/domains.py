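"""Insulation scores, TAD calling and domain-score dynamics.

TAD borders are minima of the insulation score: for each bin, the mean
contact value in a square window across the diagonal (upstream x downstream)
is taken, log2-normalized to the chromosome mean, smoothed with a 7-bin
moving average, and strict local minima below a fixed cutoff (-0.086 by
default) become borders.  TADs tile the unmasked territory between
consecutive borders.

The domain score of a TAD is the fraction of its cis contacts that are
internal; the relative domain score across a differentiation/reprogramming
series, rel = (mid - start) / (end - start), measures how far each TAD has
progressed from the start state to the end state and is the quantity used to
test whether an intermediate Hi-C map behaves like a homogeneous intermediate
state or like a mixture of start and end cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .contact_matrix import ContactMatrix

__all__ = [
    "InsulationTrack",
    "insulation_score",
    "smooth_insulation",
    "call_tad_borders",
    "tads_from_borders",
    "domain_score",
    "relative_domain_score",
    "classify_tads_early_late",
    "relative_metric_per_tad",
]


@dataclass
class InsulationTrack:
    raw: np.ndarray
    window: int
    resolution: int
    smoothed: np.ndarray | None = None


def insulation_score(matrix: ContactMatrix, window_bins: int = 10) -> InsulationTrack:
    """Square-window insulation score.

    For each bin b where the full window fits, S(b) is the mean contact value
    in the ``window_bins`` x ``window_bins`` square spanning
    (b-window .. b-1) x (b+1 .. b+window); the raw score is
    log2(S(b) / mean of S over eligible bins).  Bins whose window is fully
    masked (or that are masked themselves) are NaN.
    """
    n = matrix.n_bins
    w = window_bins
    if n < 2 * w + 1:
        raise ValueError("chromosome shorter than 2*window+1 bins")
    vals = matrix.values
    keep = matrix.unmasked
    s = np.full(n, np.nan)
    for b in range(w, n - w):
        if not keep[b]:
            continue
        block = vals[b - w: b, b + 1: b + w + 1]
        finite = np.isfinite(block)
        if finite.any():
            s[b] = block[finite].mean()
    mean_s = np.nanmean(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(np.isfinite(s) & (s > 0), np.log2(s / mean_s), np.nan)
    return InsulationTrack(raw=raw, window=w, resolution=matrix.resolution)


def smooth_insulation(track: InsulationTrack, span: int = 7) -> InsulationTrack:
    """Centred moving average, shrinking symmetrically at edges and gaps.

    Each finite bin is replaced by the mean of the finite values within
    ``span // 2`` bins on either side; bins that are NaN in the raw track
    stay NaN.
    """
    raw = track.raw
    half = span // 2
    n = len(raw)
    smoothed = np.full(n, np.nan)
    for b in range(n):
        if not np.isfinite(raw[b]):
            continue
        lo, hi = max(0, b - half), min(n, b + half + 1)
        window = raw[lo:hi]
        smoothed[b] = window[np.isfinite(window)].mean()
    return InsulationTrack(raw=raw, window=track.window,
                           resolution=track.resolution, smoothed=smoothed)


def call_tad_borders(track: InsulationTrack, cutoff: float = -0.086) -> np.ndarray:
    """Bins that are strict local minima of the smoothed score below cutoff.

    A bin (or plateau of equal bins, in which case the leftmost wins) is a
    border when its smoothed value is lower than both nearest finite
    neighbours and strictly below ``cutoff``.
    """
    s = track.smoothed if track.smoothed is not None else track.raw
    finite_idx = np.flatnonzero(np.isfinite(s))
    borders = []
    m = len(finite_idx)
    i = 0
    while i < m:
        j = i
        while j + 1 < m and s[finite_idx[j + 1]] == s[finite_idx[i]]:
            j += 1
        v = s[finite_idx[i]]
        left_ok = i > 0 and s[finite_idx[i - 1]] > v
        right_ok = j < m - 1 and s[finite_idx[j + 1]] > v
        if left_ok and right_ok and v < cutoff:
            borders.append(int(finite_idx[i]))  # leftmost bin of the plateau
        i = j + 1
    return np.array(borders, dtype=int)


def tads_from_borders(
    borders: np.ndarray, bins, min_bins: int = 3
) -> pd.DataFrame:
    """TAD intervals delimited by borders and mask-gap/chromosome ends.

    Contiguous unmasked stretches are cut at every border bin (the border bin
    starts the downstream TAD); TADs shorter than ``min_bins`` bins are
    discarded.  Returns a BED-like frame with bin-index bounds
    (``bin_start`` inclusive, ``bin_end`` exclusive).
    """
    masked = bins.masked
    n = len(masked)
    border_set = set(int(b) for b in borders)
    records = []
    start = None
    for b in range(n + 1):
        at_end = b == n or masked[b]
        if start is not None and (at_end or b in border_set):
            if b - start >= min_bins:
                records.append((start, b))
            start = None if at_end else b
        elif start is None and not at_end:
            start = b
    df = pd.DataFrame(records, columns=["bin_start", "bin_end"])
    df.insert(0, "chrom", bins.chrom)
    df["start"] = bins.starts[df["bin_start"]] if len(df) else []
    df["end"] = bins.ends[df["bin_end"] - 1] if len(df) else []
    return df


def domain_score(matrix: ContactMatrix, tads: pd.DataFrame) -> np.ndarray:
    """Fraction of each TAD's cis contacts that are intra-TAD.

    score(T) = sum of contact values over (i in T, j in T) divided by the sum
    over (i in T, all j), diagonal excluded.  TADs with zero total contacts
    are NaN.  Invariant to global matrix scaling; always in [0, 1].
    """
    vals = np.where(np.isfinite(matrix.values), matrix.values, 0.0).copy()
    np.fill_diagonal(vals, 0.0)
    scores = np.full(len(tads), np.nan)
    row_tot = vals.sum(axis=1)
    for t, (b0, b1) in enumerate(tads[["bin_start", "bin_end"]].itertuples(index=False)):
        intra = vals[b0:b1, b0:b1].sum()
        total = row_tot[b0:b1].sum()
        if total > 0:
            scores[t] = intra / total
    return scores


def relative_domain_score(
    ds_start: np.ndarray, ds_mid: np.ndarray, ds_end: np.ndarray, eps: float = 0.01
) -> np.ndarray:
    """Per-TAD progress of the mid state: (mid - start) / (end - start).

    TADs whose start and end scores differ by less than ``eps`` carry no
    signal and are NaN.
    """
    ds_start, ds_mid, ds_end = (np.asarray(a, dtype=float) for a in (ds_start, ds_mid, ds_end))
    if not (len(ds_start) == len(ds_mid) == len(ds_end)):
        raise ValueError("score vectors have different lengths")
    denom = ds_end - ds_start
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (ds_mid - ds_start) / denom
    rel[np.abs(denom) < eps] = np.nan
    return rel


def classify_tads_early_late(
    relative_scores: np.ndarray, seed: int = 0, threshold: float = 0.2
) -> tuple[np.ndarray, float, float]:
    """Split TADs into early/late restructurers by 1-D k-means (k=2).

    The cluster with the larger centre is "early".  Also reports the fraction
    of TADs with relative score above ``threshold`` as a model-free
    cross-check.  Returns (labels, fraction_early_kmeans, fraction_above).
    """
    rel = np.asarray(relative_scores, dtype=float)
    finite = np.isfinite(rel)
    x = rel[finite]
    if x.size < 4:
        raise ValueError("need at least 4 finite relative scores")
    if np.ptp(x) == 0:
        raise ValueError("all relative scores identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x.reshape(-1, 1))
    early_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    labels = np.full(len(rel), "", dtype=object)
    labels[finite] = np.where(km.labels_ == early_cluster, "early", "late")
    frac_early = float((km.labels_ == early_cluster).mean())
    frac_above = float((x > threshold).mean())
    return labels, frac_early, frac_above


def relative_metric_per_tad(
    values: np.ndarray,
    start: int = 0,
    end: int = -1,
    min_count: float | None = None,
    eps: float = 1e-9,
) -> np.ndarray:
    """Relative per-TAD trajectory of an omics metric across timepoints.

    ``values`` is (n_tads, n_timepoints); rel(t) = (x_t - x_start) /
    (x_end - x_start), mapping the start state to 0 and the end state to 1.
    TADs with fewer than ``min_count`` units at the end state (e.g. a minimum
    peak count) or with a flat start-to-end change are excluded (NaN rows).
    """
    x = np.asarray(values, dtype=float)
    end_idx = x.shape[1] + end if end < 0 else end
    x_start, x_end = x[:, start], x[:, end_idx]
    denom = x_end - x_start
    out = np.full_like(x, np.nan)
    ok = np.abs(denom) > eps
    if min_count is not None:
        ok &= x_end >= min_count
    out[ok] = (x[ok] - x_start[ok, None]) / denom[ok, None]
    return out
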