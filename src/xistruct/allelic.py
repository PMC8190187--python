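"""Allele-resolved expression and accessibility statistics.

In a hybrid cell line the two parental alleles (here called ``mus`` and
``cas``) are distinguished by sequence polymorphisms, so every gene carries
an allelic expression ratio r = mus / (mus + cas): 0 means the mus allele
(the inactive X) is fully silenced, 0.5 means biallelic expression.  This
module implements the read-assignment decision rule, the gene filtering
funnel (SNP-informative -> sufficiently cas-expressed), escapee and
reactivation calls at the r > 0.14 cutoff, and the ATAC-accessibility
dynamics metrics (relative differential peaks, promoter accessibility,
peak density per spatial cluster).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecordPair",
    "assign_allele",
    "allelic_ratio",
    "filter_expressed_genes",
    "absolute_allelic_expression",
    "classify_allelic_status",
    "fraction_reactivated_per_cluster",
    "distance_to_nearest_escapee",
    "relative_differential_peaks",
    "promoter_accessibility",
    "peak_density_per_cluster",
]

ESCAPEE_CUTOFF = 0.14
BIALLELIC_RANGE = (0.4, 0.6)


class AlignmentRecordPair(NamedTuple):
    """One read aligned independently against the two parental genomes."""

    mapq1: int
    score1: int
    mapq2: int
    score2: int


def assign_allele(pair: AlignmentRecordPair) -> str:
    """Assign a read to a parental genome from its two alignments.

    Unmapped if the mapping quality is 0 in both genomes; otherwise the
    genome with the strictly greater alignment score wins; equal scores are
    ambiguous.
    """
    if pair.mapq1 == 0 and pair.mapq2 == 0:
        return "unmapped"
    if pair.score1 > pair.score2:
        return "genome1"
    if pair.score2 > pair.score1:
        return "genome2"
    return "ambiguous"


def allelic_ratio(mus, cas):
    """mus / (mus + cas); NaN where both are zero."""
    mus = np.asarray(mus, dtype=float)
    cas = np.asarray(cas, dtype=float)
    if (mus < 0).any() or (cas < 0).any():
        raise ValueError("negative counts")
    tot = mus + cas
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(tot > 0, mus / tot, np.nan)
    return float(r) if r.ndim == 0 else r


def filter_expressed_genes(
    table: pd.DataFrame,
    cas_column: str = "cas_count",
    pct: float = 0.25,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Two-stage gene filter with funnel counts.

    Stage 1 keeps SNP-informative genes; stage 2 keeps genes whose cas
    expression is at or above the ``pct`` quantile (linear-interpolation
    definition) of cas expression among stage-1 genes.  Returns the filtered
    table and the counts at each funnel stage.
    """
    if len(table) == 0:
        raise ValueError("empty gene table")
    stage1 = table[table["snp_informative"].astype(bool)]
    threshold = float(np.quantile(stage1[cas_column].to_numpy(dtype=float), pct))
    stage2 = stage1[stage1[cas_column] >= threshold]
    funnel = {
        "input": int(len(table)),
        "snp_informative": int(len(stage1)),
        "expressed": int(len(stage2)),
    }
    return stage2.reset_index(drop=True), funnel


def absolute_allelic_expression(bulk, ratio) -> tuple[np.ndarray, np.ndarray]:
    """Allele-level expression from bulk counts: (bulk*r, bulk*(1-r))."""
    bulk = np.asarray(bulk, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    return bulk * ratio, bulk * (1 - ratio)


def classify_allelic_status(
    ratios: pd.DataFrame,
    reference: str,
    endpoints: tuple[str, str],
    escapee_cutoff: float = ESCAPEE_CUTOFF,
    biallelic: tuple[float, float] = BIALLELIC_RANGE,
) -> pd.DataFrame:
    """Escapee / reactivation / biallelic flags from per-sample allelic ratios.

    ``ratios`` has one row per gene, one column per sample.  A gene escapes
    X-inactivation when its ratio in the ``reference`` (inactive-state)
    sample exceeds ``escapee_cutoff`` (strict); it counts as reactivated in
    sample s when ratio_s exceeds the same cutoff.  ``biallelic_endpoint`` is
    True when both endpoint ratios lie strictly inside the ``biallelic``
    interval; reactivation analyses are restricted to such genes.
    """
    for s in (reference, *endpoints):
        if s not in ratios.columns:
            raise ValueError(f"missing sample column {s!r}")
    out = pd.DataFrame(index=ratios.index)
    out["escapee"] = ratios[reference] > escapee_cutoff
    for s in ratios.columns:
        out[f"reactivated_{s}"] = ratios[s] > escapee_cutoff
    lo, hi = biallelic
    out["biallelic_endpoint"] = (
        (ratios[endpoints[0]] > lo) & (ratios[endpoints[0]] < hi)
        & (ratios[endpoints[1]] > lo) & (ratios[endpoints[1]] < hi)
    )
    return out


def fraction_reactivated_per_cluster(
    flags: pd.DataFrame,
    cluster_of_gene: pd.Series,
    timepoints: list[str],
    eligible: pd.Series | None = None,
) -> pd.DataFrame:
    """Fraction of eligible genes reactivated, per cluster and timepoint.

    ``eligible`` defaults to the biallelic-endpoint genes.  Clusters with no
    eligible gene are NaN.
    """
    if eligible is None:
        eligible = flags["biallelic_endpoint"]
    keep = eligible.astype(bool)
    clusters = sorted(cluster_of_gene[keep].dropna().unique())
    out = pd.DataFrame(index=clusters, columns=timepoints, dtype=float)
    for c in clusters:
        genes = keep & (cluster_of_gene == c)
        n = int(genes.sum())
        for t in timepoints:
            out.loc[c, t] = flags.loc[genes, f"reactivated_{t}"].sum() / n if n else np.nan
    return out


def distance_to_nearest_escapee(
    tss: pd.Series, escapee: pd.Series
) -> pd.Series:
    """TSS distance from each gene to the nearest escapee (self excluded)."""
    esc_pos = np.sort(tss[escapee.astype(bool)].to_numpy(dtype=np.int64))
    if esc_pos.size == 0:
        raise ValueError("no escapees")
    out = pd.Series(np.nan, index=tss.index)
    for g in tss.index:
        pos = tss[g]
        others = esc_pos if not escapee[g] else esc_pos[esc_pos != pos]
        if others.size:
            out[g] = np.abs(others - pos).min()
    return out


def _midpoints(peaks: pd.DataFrame) -> np.ndarray:
    return ((peaks["start"].to_numpy(np.int64) + peaks["end"].to_numpy(np.int64)) // 2)


def _cluster_of_position(pos: np.ndarray, bins, clustering) -> np.ndarray:
    return clustering.cluster_id[np.asarray(bins.bin_of(pos))]


def _overlaps_any(peaks: pd.DataFrame, baseline: pd.DataFrame) -> np.ndarray:
    """True for each peak overlapping (>= 1 bp) any baseline interval."""
    if len(baseline) == 0:
        return np.zeros(len(peaks), dtype=bool)
    bs = np.sort(baseline["start"].to_numpy(np.int64))
    order = np.argsort(baseline["start"].to_numpy(np.int64))
    be = baseline["end"].to_numpy(np.int64)[order]
    # running max of ends handles nested intervals
    be_max = np.maximum.accumulate(be)
    out = np.zeros(len(peaks), dtype=bool)
    for i, (s, e) in enumerate(peaks[["start", "end"]].itertuples(index=False)):
        j = np.searchsorted(bs, e, side="left")  # baseline starts before peak end
        out[i] = j > 0 and be_max[j - 1] > s
    return out


def relative_differential_peaks(
    peak_sets: dict[str, pd.DataFrame],
    baseline_sample: str,
    end_sample: str,
    bins,
    clustering,
) -> pd.DataFrame:
    """Per-cluster accumulation of new accessibility peaks over a time course.

    Differential peaks of a sample are its peaks with no overlap (>= 1 bp
    disqualifies) with any baseline peak; peaks are assigned to spatial
    clusters by midpoint.  value(cluster, sample) = differential peaks of the
    sample in the cluster / differential peaks of the end sample in the
    cluster, so the baseline is 0 and the end sample 1 by construction.
    Clusters where the end sample has no differential peaks are NaN.
    """
    baseline = peak_sets[baseline_sample]
    diff_counts: dict[str, pd.Series] = {}
    clusters = sorted(int(c) for c in np.unique(clustering.cluster_id) if c != -1)
    for sample, peaks in peak_sets.items():
        diff = peaks[~_overlaps_any(peaks, baseline)]
        labels = _cluster_of_position(_midpoints(diff), bins, clustering) if len(diff) else np.array([], dtype=int)
        diff_counts[sample] = pd.Series(labels).value_counts().reindex(clusters, fill_value=0)
    end_counts = diff_counts[end_sample]
    out = pd.DataFrame(index=clusters, columns=list(peak_sets), dtype=float)
    for sample in peak_sets:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sample] = np.where(end_counts > 0, diff_counts[sample] / end_counts, np.nan)
    return out


def promoter_accessibility(
    track: pd.DataFrame, tss: pd.Series, half_window: int = 2000,
    chrom_length: int | None = None,
) -> pd.Series:
    """Summed signal in a +/- ``half_window`` bp window around each TSS.

    ``track`` is bedGraph-like (chrom, start, end, value); each interval
    contributes value x overlap-length with [TSS - half_window,
    TSS + half_window).
    """
    ts = track["start"].to_numpy(np.int64)
    te = track["end"].to_numpy(np.int64)
    tv = track["value"].to_numpy(float)
    out = pd.Series(0.0, index=tss.index)
    for g, pos in tss.items():
        if pos < 0 or (chrom_length is not None and pos >= chrom_length):
            raise ValueError(f"TSS of {g!r} off chromosome")
        lo, hi = pos - half_window, pos + half_window
        ov = np.minimum(te, hi) - np.maximum(ts, lo)
        pos_ov = ov > 0
        out[g] = float((tv[pos_ov] * ov[pos_ov]).sum())
    return out


def peak_density_per_cluster(
    peaks: pd.DataFrame, bins, clustering
) -> pd.Series:
    """Peaks per megabase of cluster territory (midpoint assignment)."""
    clusters = sorted(int(c) for c in np.unique(clustering.cluster_id) if c != -1)
    labels = _cluster_of_position(_midpoints(peaks), bins, clustering)
    counts = pd.Series(labels).value_counts().reindex(clusters, fill_value=0)
    widths = bins.ends - bins.starts
    out = pd.Series(np.nan, index=clusters, dtype=float)
    for c in clusters:
        territory = widths[clustering.cluster_id == c].sum()
        if territory == 0:
            raise ValueError(f"cluster {c} has empty territory")
        out[c] = counts[c] / (territory / 1e6)
    return out
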