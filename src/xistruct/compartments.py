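"""A/B compartment calling on mega-domain-split contact matrices.

The inactive X folds into two mega-domains split at the *Dxz4* boundary
(~75.6 Mb), so the leading eigenvector of a whole-chromosome correlation
matrix captures the mega-domains rather than A/B compartments.  Compartment
calling is therefore run separately on the two sub-matrices on either side of
the split point: each sub-matrix is distance-normalized (observed/expected),
converted to a Pearson correlation matrix over unmasked bins, and its first
principal component taken as the compartment eigenvector, oriented so that
positive values mark the GC-rich (A-like, open) compartment.

Raw PC1 is then calibrated to [-1, +1] by a two-component Gaussian mixture:
values are centred at the density-intersection point between the two fitted
components and the positive/negative halves rescaled by their extrema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, pearsonr
from sklearn.mixture import GaussianMixture

from .contact_matrix import OE, BinTable, ContactMatrix, observed_over_expected

__all__ = [
    "CompartmentTrack",
    "SaddleSummary",
    "split_pca_compartments",
    "calibrate_pc1_gmm",
    "gmm_intersection",
    "count_compartments",
    "saddle_aggregate",
    "compartment_strength",
]


@dataclass
class CompartmentTrack:
    """Per-bin compartment eigenvector with optional calibration.

    ``raw_pc1`` is NaN at masked bins.  After calibration, ``calibrated`` lies
    in [-1, +1] and ``labels`` holds 'A' (positive), 'B' (negative) or '' at
    missing bins.
    """

    raw_pc1: np.ndarray
    split_point: int | None = None
    calibrated: np.ndarray | None = None
    labels: np.ndarray | None = None
    sample: str = ""
    allele: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.raw_pc1)


@dataclass
class SaddleSummary:
    grid: np.ndarray
    strength_aa: float = np.nan
    strength_bb: float = np.nan
    strength_ab: float = np.nan
    overall: float = np.nan


def _leading_eigenvector(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    return vecs[:, np.argmax(vals)]


def _pc1_one_segment(
    oe: np.ndarray, keep: np.ndarray, gc: np.ndarray | None
) -> np.ndarray:
    """PC1 of the Pearson correlation matrix of one sub-matrix's unmasked bins."""
    if keep.sum() < 10:
        raise ValueError("fewer than 10 unmasked bins in sub-matrix")
    sub = oe[np.ix_(keep, keep)]
    sub = np.where(np.isfinite(sub), sub, np.nanmean(sub))
    sd = sub.std(axis=1)
    if (sd == 0).all():
        raise ValueError("zero-variance correlation matrix")
    # constant rows would produce NaN correlations; nudge them out of the way
    sub[sd == 0] += np.random.default_rng(0).normal(0, 1e-12, size=(int((sd == 0).sum()), sub.shape[1]))
    corr = np.corrcoef(sub)
    pc1 = _leading_eigenvector(corr)
    if gc is not None:
        r = pearsonr(pc1, gc[keep])[0]
        if np.isfinite(r) and r < 0:
            pc1 = -pc1
    elif pc1.sum() < 0:  # no GC track: deterministic sign only
        pc1 = -pc1
    full = np.full(len(keep), np.nan)
    full[keep] = pc1
    return full


def split_pca_compartments(
    matrix: ContactMatrix,
    split_point: int | None = None,
    gc: np.ndarray | None = None,
) -> CompartmentTrack:
    """Compartment eigenvector per mega-domain arm.

    With ``split_point`` set (base pairs), PC1 is computed independently on
    the two sub-matrices left and right of it and concatenated; this removes
    the dominant mega-domain signal so the eigenvector reads out A/B
    checkerboarding.  With ``split_point=None`` on a mega-domain matrix, PC1
    instead flips sign at the mega-domain boundary.

    ``gc`` is a per-bin GC-content track used to orient each arm's
    eigenvector (A = GC-rich = positive).
    """
    keep = matrix.unmasked
    n = matrix.n_bins
    raw = np.full(n, np.nan)
    if split_point is None:
        segments = [np.arange(n)]
    else:
        split_bin = int(matrix.bins.bin_of(split_point))
        segments = [np.arange(split_bin), np.arange(split_bin, n)]
    for seg in segments:
        seg_keep = keep[seg]
        sub_vals = matrix.values[np.ix_(seg, seg)]
        if matrix.state == OE:
            seg_oe = sub_vals
        else:
            # distance decay must be estimated within the sub-matrix: the
            # whole-chromosome decay is distorted by inter-mega-domain pairs
            sub_bins = BinTable(matrix.bins.df.iloc[seg].reset_index(drop=True))
            sub = ContactMatrix(sub_bins, sub_vals, matrix.state, matrix.allele)
            seg_oe = observed_over_expected(sub)[0].values
        seg_gc = gc[seg] if gc is not None else None
        raw[seg] = _pc1_one_segment(seg_oe, seg_keep, seg_gc)
    return CompartmentTrack(raw_pc1=raw, split_point=split_point, allele=matrix.allele)


def gmm_intersection(
    weights: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> float:
    """Density-intersection point between two Gaussian components.

    Root of ``w1*phi1(x) = w2*phi2(x)`` between the two means, located by a
    dense scan for a sign change followed by bisection.
    """
    order = np.argsort(means)
    w, m, s = weights[order], means[order], sds[order]
    if np.isclose(m[0], m[1]):
        raise ValueError("component means coincide")

    def diff(x: float) -> float:
        return w[0] * norm.pdf(x, m[0], s[0]) - w[1] * norm.pdf(x, m[1], s[1])

    grid = np.linspace(m[0], m[1], 2048)
    vals = diff(grid)
    sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if sign_change.size == 0:
        # components too imbalanced for a crossing between the means
        return float(grid[np.argmin(np.abs(vals))])
    i = sign_change[0]
    return float(brentq(diff, grid[i], grid[i + 1], xtol=1e-12))


def calibrate_pc1_gmm(
    track: CompartmentTrack | np.ndarray,
    trim: float = 0.05,
    seed: int = 0,
) -> CompartmentTrack:
    """Calibrate raw PC1 to [-1, +1] via a two-component Gaussian mixture.

    The extreme ``trim`` fraction of values (half per tail) is removed for
    fitting only.  An unequal-variance two-component mixture is fit by EM
    (10 restarts); all values are centred at the density-intersection point
    between the components, then positive values are divided by the maximum
    positive value and negative values by the absolute minimum.  Bins with
    calibrated value > 0 are labelled 'A', < 0 'B'.
    """
    if isinstance(track, np.ndarray):
        track = CompartmentTrack(raw_pc1=np.asarray(track, dtype=float))
    raw = track.raw_pc1
    finite = np.isfinite(raw)
    x = raw[finite]
    if x.size < 20:
        raise ValueError("need at least 20 finite PC1 values")
    if np.unique(x).size < 2:
        raise ValueError("fewer than 2 distinct PC1 values")
    k = int(np.floor(x.size * trim / 2))
    xs = np.sort(x)
    fit_x = xs[k: x.size - k] if k > 0 else xs
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=10, tol=1e-6,
        random_state=seed, max_iter=500,
    ).fit(fit_x.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    try:
        x_star = gmm_intersection(gmm.weights_, means, sds)
    except ValueError:
        warnings.warn("GMM component means coincide; centring at trimmed median")
        x_star = float(np.median(fit_x))
    centred = raw - x_star
    calibrated = np.full_like(raw, np.nan)
    pos = finite & (centred > 0)
    neg = finite & (centred < 0)
    if pos.any():
        calibrated[pos] = centred[pos] / centred[pos].max()
    if neg.any():
        calibrated[neg] = centred[neg] / abs(centred[neg].min())
    calibrated[finite & (centred == 0)] = 0.0
    labels = np.full(len(raw), "", dtype=object)
    labels[pos] = "A"
    labels[neg] = "B"
    return CompartmentTrack(
        raw_pc1=raw, split_point=track.split_point, calibrated=calibrated,
        labels=labels, sample=track.sample, allele=track.allele,
    )


def count_compartments(
    track: CompartmentTrack,
    bins,
    min_segment: int = 300_000,
) -> tuple[int, int, pd.DataFrame]:
    """Count A and B compartment segments of at least ``min_segment`` bp.

    Consecutive unmasked bins with the same label are merged into segments
    (masked bins break a run); segments shorter than ``min_segment`` are
    dropped without re-merging their neighbours.  Returns ``(n_A, n_B,
    segments)`` with segments as a BED-like frame.
    """
    labels = track.labels
    if labels is None:
        raise ValueError("track must be calibrated first")
    starts, ends = bins.starts, bins.ends
    records = []
    run_label, run_start, run_end = None, None, None
    for i in range(len(labels)):
        lab = labels[i] if labels[i] in ("A", "B") else None
        if lab is not None and lab == run_label and starts[i] == run_end:
            run_end = ends[i]
        else:
            if run_label is not None:
                records.append((run_label, run_start, run_end))
            run_label = lab
            run_start, run_end = (starts[i], ends[i]) if lab else (None, None)
            if lab is None:
                run_label = None
    if run_label is not None:
        records.append((run_label, run_start, run_end))
    seg = pd.DataFrame(records, columns=["label", "start", "end"])
    if len(seg):
        seg = seg[(seg["end"] - seg["start"]) >= min_segment].reset_index(drop=True)
        seg.insert(0, "chrom", bins.chrom)
    else:
        seg = pd.DataFrame(columns=["chrom", "label", "start", "end"])
    n_a = int((seg["label"] == "A").sum())
    n_b = int((seg["label"] == "B").sum())
    return n_a, n_b, seg


def _pc1_categories(pc1: np.ndarray, n_cat: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count rank categories of finite PC1 values (ties by bin index)."""
    finite_idx = np.flatnonzero(np.isfinite(pc1))
    order = finite_idx[np.argsort(pc1[finite_idx], kind="stable")]
    cats = np.full(len(pc1), -1, dtype=int)
    for c, chunk in enumerate(np.array_split(order, n_cat)):
        cats[chunk] = c
    return cats, finite_idx


def saddle_aggregate(matrix: ContactMatrix, pc1: np.ndarray, n_cat: int = 50) -> np.ndarray:
    """Saddle grid: mean log2 O/E between rank categories of PC1.

    Bins are assigned to ``n_cat`` equal-count categories by ascending PC1;
    cell (c1, c2) is the mean log2 O/E over all unmasked bin pairs (i != j)
    in those categories.  The grid is symmetrized; empty cells are NaN.
    """
    if matrix.state != OE:
        matrix = observed_over_expected(matrix)[0]
    cats, _ = _pc1_categories(pc1, n_cat)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.log2(matrix.values)
    np.fill_diagonal(logv, np.nan)
    grid = np.full((n_cat, n_cat), np.nan)
    members = [np.flatnonzero(cats == c) for c in range(n_cat)]
    for a in range(n_cat):
        for b in range(a, n_cat):
            block = logv[np.ix_(members[a], members[b])]
            block = block[np.isfinite(block)]
            if block.size:
                grid[a, b] = grid[b, a] = block.mean()
    return grid


def compartment_strength(
    matrix: ContactMatrix, pc1: np.ndarray, frac: float = 0.2
) -> SaddleSummary:
    """Compartmentalization strength from extreme-PC1 bins.

    The top ``frac`` of bins by PC1 form the A class and the bottom ``frac``
    the B class; each strength is the median log2 O/E over the corresponding
    pairs, and the overall strength is ``(AA + BB)/2 - AB``.
    """
    if matrix.state != OE:
        matrix = observed_over_expected(matrix)[0]
    finite_idx = np.flatnonzero(np.isfinite(pc1))
    n_take = int(round(len(finite_idx) * frac))
    if n_take < 5:
        raise ValueError("fewer than 5 bins per class")
    order = finite_idx[np.argsort(pc1[finite_idx], kind="stable")]
    b_bins, a_bins = order[:n_take], order[-n_take:]
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.log2(matrix.values)
    np.fill_diagonal(logv, np.nan)

    def med(rows: np.ndarray, cols: np.ndarray) -> float:
        block = logv[np.ix_(rows, cols)]
        block = block[np.isfinite(block)]
        return float(np.median(block)) if block.size else np.nan

    aa, bb, ab = med(a_bins, a_bins), med(b_bins, b_bins), med(a_bins, b_bins)
    overall = (aa + bb) / 2 - ab
    return SaddleSummary(grid=np.empty((0, 0)), strength_aa=aa, strength_bb=bb,
                         strength_ab=ab, overall=overall)
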