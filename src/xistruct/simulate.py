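"""Synthetic allele-resolved data with planted ground truth.

Every analysis stage in this package has a parameter-recovery test built on
these generators, so the pipeline is verifiable without downloading any
sequencing data.  The contact-map generator plants the structural motifs of
an inactive X undergoing reprogramming: two mega-domains split at a boundary,
an A/B checkerboard of tunable contrast, TADs whose intra-domain enrichment
is attenuated per pseudo-timepoint (the Xi starts with weak TADs that return
during reactivation), a power-law distance decay, Poisson count noise and a
masked-bin pattern.  The expected matrix is analytic,

    E(i, j) = depth_scale * (1 + |i - j|)^(-alpha) * C(i, j) * T(i, j) * M(i, j),

with C the compartment checkerboard factor (1 + contrast for same-label
pairs, 1 - contrast otherwise), T the intra-TAD enrichment and M the
inter-mega-domain damping, so every recovery test has a known target before
sampling noise.  The expression generator plants an escapee set and staged
reactivation of silenced genes; the peak generator plants accessibility
peaks accruing monotonically over pseudo-time, concentrated per spatial
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contact_matrix import RAW, BinTable, ContactMatrix
from .subcompartments import SpatialClustering

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_contact_maps",
    "generate_allelic_counts",
    "generate_peak_sets",
    "planted_correlation_matrix",
    "make_worked_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the real system: a ~170-Mb X chromosome binned at 100 kb
    (1700 bins), mega-domain boundary at 75.6 Mb, compartment contrast 0.3 at
    5e6 total contacts, a reprogramming series from an inactive-X-like start
    state (TADs attenuated away) to an active-like end state, 806 genes of
    which ~69% carry informative polymorphisms, and a deep (>=50 reads/gene)
    expression survey with a planted 10% escapee fraction.
    """

    seed: int = 0
    # chromosome / binning
    chrom: str = "chrX"
    chrom_length: int = 170_000_000
    resolution: int = 100_000
    megadomain_boundary: int = 75_600_000
    megadomain_damping: float = 0.4  # cross-boundary contact multiplier
    # compartments
    compartment_segment_mb: tuple[float, float] = (2.0, 8.0)
    compartment_contrast: float = 0.3
    # TADs
    tad_size_mb: tuple[float, float] = (0.4, 1.6)
    tad_fold: float = 2.0  # intra-TAD fold enrichment at full strength
    tad_attenuation: tuple[float, ...] = (0.0, 0.5, 1.0, 1.0)  # per timepoint
    # decay / depth / masking
    decay_exponent: float = 1.0
    depth: float = 5_000_000.0
    masked_fraction: float = 0.05
    # pseudo-time
    timepoints: tuple[str, ...] = ("NPC", "D5", "iPSC", "ESC")
    # genes
    n_genes: int = 806
    snp_informative_frac: float = 558 / 806
    escapee_frac: float = 0.10
    gene_depth: float = 200.0  # mean informative reads per gene
    nb_dispersion: float = 0.1
    silenced_ratio: float = 0.02
    escapee_ratio: float = 0.30
    biallelic_ratio: float = 0.50
    # peaks
    n_clusters: int = 12
    n_baseline_peaks: int = 200
    n_new_peaks: int = 300
    peak_width: int = 300
    peak_height: float = 5.0


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset."""

    compartment_label: np.ndarray | None = None  # 'A'/'B' per bin
    cluster_id: np.ndarray | None = None  # 1..n_clusters per bin
    tad_borders: np.ndarray | None = None  # bin indices
    masked: np.ndarray | None = None
    gc: np.ndarray | None = None
    escapees: list[str] = field(default_factory=list)
    reactivation_time: dict[str, str] = field(default_factory=dict)


def _segment_layout(rng: np.random.Generator, n_bins: int, lo_bins: int, hi_bins: int) -> np.ndarray:
    """Alternating A/B segment labels covering n_bins."""
    labels = np.empty(n_bins, dtype=object)
    pos, lab = 0, "A"
    while pos < n_bins:
        size = int(rng.integers(lo_bins, hi_bins + 1))
        labels[pos: pos + size] = lab
        lab = "B" if lab == "A" else "A"
        pos += size
    return labels


def _tad_layout(rng: np.random.Generator, labels: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """TAD border bins nested inside compartment segments (never crossing them)."""
    n = len(labels)
    seg_starts = [0] + [i for i in range(1, n) if labels[i] != labels[i - 1]]
    seg_bounds = seg_starts + [n]
    borders = []
    for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
        pos = s
        while True:
            pos += int(rng.integers(lo, hi + 1))
            if pos >= e - lo // 2:
                break
            borders.append(pos)
        borders.append(e)  # segment edges are TAD borders too
    return np.array(sorted(set(b for b in borders if 0 < b < n)), dtype=int)


def plant_structure(config: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the planted chromosome layout (shared across timepoints/alleles)."""
    rng = rng or np.random.default_rng(config.seed)
    n = int(np.ceil(config.chrom_length / config.resolution))
    lo = max(1, int(config.compartment_segment_mb[0] * 1e6 / config.resolution))
    hi = max(lo, int(config.compartment_segment_mb[1] * 1e6 / config.resolution))
    labels = _segment_layout(rng, n, lo, hi)
    t_lo = max(2, int(config.tad_size_mb[0] * 1e6 / config.resolution))
    t_hi = max(t_lo, int(config.tad_size_mb[1] * 1e6 / config.resolution))
    borders = _tad_layout(rng, labels, t_lo, t_hi)
    masked = np.zeros(n, dtype=bool)
    n_mask = int(round(config.masked_fraction * n))
    if n_mask:
        masked[rng.choice(n, size=n_mask, replace=False)] = True
    gc = np.where(labels == "A", 0.45, 0.40) + rng.normal(0, 0.005, n)
    # cluster ids: cycle 1..n_clusters over compartment segments
    cluster = np.zeros(n, dtype=int)
    seg_id = np.cumsum(np.r_[True, labels[1:] != labels[:-1]]) - 1
    cluster = (seg_id % config.n_clusters) + 1
    return GroundTruth(compartment_label=labels, cluster_id=cluster,
                       tad_borders=borders, masked=masked, gc=gc)


def expected_matrix(
    config: SimulationConfig, truth: GroundTruth, attenuation: float = 1.0,
    damping: float | None = None,
) -> np.ndarray:
    """Analytic expected contact matrix for one allele/timepoint."""
    n = len(truth.compartment_label)
    idx = np.arange(n)
    dist = np.abs(np.subtract.outer(idx, idx))
    base = (1.0 + dist) ** (-config.decay_exponent)
    same = np.equal.outer(truth.compartment_label, truth.compartment_label)
    comp = np.where(same, 1.0 + config.compartment_contrast, 1.0 - config.compartment_contrast)
    tad_id = np.searchsorted(truth.tad_borders, idx, side="right")
    same_tad = np.equal.outer(tad_id, tad_id)
    fold = 1.0 + (config.tad_fold - 1.0) * attenuation
    tad = np.where(same_tad, fold, 1.0)
    damping = config.megadomain_damping if damping is None else damping
    split_bin = config.megadomain_boundary // config.resolution
    side = idx >= split_bin
    cross = np.not_equal.outer(side, side)
    mega = np.where(cross, damping, 1.0)
    e = base * comp * tad * mega
    e *= config.depth / e.sum()
    return e


def _sample_poisson_symmetric(rng: np.random.Generator, e: np.ndarray) -> np.ndarray:
    n = e.shape[0]
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(e[iu, ju])
    m = np.zeros((n, n))
    m[iu, ju] = counts
    m = np.triu(m) + np.triu(m, 1).T
    return m


def generate_contact_maps(
    config: SimulationConfig,
    alleles: tuple[str, ...] = ("mus", "cas"),
) -> tuple[dict[str, dict[str, ContactMatrix]], GroundTruth]:
    """Poisson-sampled contact matrices per allele per pseudo-timepoint.

    The ``mus`` (inactive-X-like) allele carries mega-domain damping and the
    per-timepoint TAD attenuation schedule; the ``cas`` (active-like) allele
    has full TADs and no mega-domain structure at every timepoint.  Masked
    bins are zeroed and flagged.  Returns ``maps[allele][timepoint]`` and the
    shared ground truth.
    """
    if len(config.tad_attenuation) != len(config.timepoints):
        raise ValueError("tad_attenuation must match timepoints")
    rng = np.random.default_rng(config.seed)
    truth = plant_structure(config, rng)
    n = len(truth.compartment_label)
    mapp = np.where(truth.masked, 0.3, 1.0)
    bins = BinTable.from_resolution(config.chrom, config.chrom_length,
                                    config.resolution, mappability=mapp)
    maps: dict[str, dict[str, ContactMatrix]] = {}
    for allele in alleles:
        maps[allele] = {}
        for t, name in enumerate(config.timepoints):
            att = config.tad_attenuation[t] if allele == "mus" else 1.0
            damp = None if allele == "mus" else 1.0
            e = expected_matrix(config, truth, attenuation=att, damping=damp)
            m = _sample_poisson_symmetric(rng, e)
            cm = ContactMatrix(bins, m, RAW, allele)
            maps[allele][name] = cm.apply_mask(truth.masked)
    return maps, truth


def generate_allelic_counts(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene allelic counts across pseudo-timepoints with planted truth.

    Escapees keep an allelic ratio of ``escapee_ratio`` (>= 0.2) at all
    times; silenced genes sit at ``silenced_ratio`` before their planted
    reactivation timepoint and at ``biallelic_ratio`` from it onward.  All
    genes are biallelic at the two endpoint samples.  Counts are negative
    binomial around the planted means; a configured fraction of genes lacks
    informative polymorphisms (zero allelic counts).
    """
    rng = np.random.default_rng(config.seed + 1)
    tp = list(config.timepoints)
    n = config.n_genes
    genes = [f"gene{g:04d}" for g in range(n)]
    tss = np.sort(rng.choice(config.chrom_length, size=n, replace=False))
    informative = rng.random(n) < config.snp_informative_frac
    escapee = informative & (rng.random(n) < config.escapee_frac)
    # silenced informative genes reactivate at a middle timepoint or the first endpoint
    react_choices = list(range(1, len(tp) - 1))
    react_idx = rng.choice(react_choices, size=n)
    truth = GroundTruth(
        escapees=[genes[g] for g in range(n) if escapee[g]],
        reactivation_time={
            genes[g]: tp[react_idx[g]]
            for g in range(n) if informative[g] and not escapee[g]
        },
    )
    mu = rng.lognormal(np.log(config.gene_depth), 0.4, size=n)
    theta = 1.0 / config.nb_dispersion

    rows: dict[str, np.ndarray] = {}
    for t, name in enumerate(tp):
        r = np.full(n, config.biallelic_ratio)
        pre = t < len(tp) - 2  # before the endpoint samples
        if pre:
            r = np.where(escapee, config.escapee_ratio,
                         np.where(t < react_idx, config.silenced_ratio,
                                  config.biallelic_ratio))
        # overdispersed total split binomially between alleles, so the
        # realized allelic ratio concentrates at the planted ratio
        total = rng.negative_binomial(theta, theta / (theta + np.maximum(mu, 1e-9)))
        mus = np.where(informative, rng.binomial(total, r), 0)
        cas = np.where(informative, total - mus, 0)
        rows[f"mus_{name}"] = mus
        rows[f"cas_{name}"] = cas
        rows[f"bulk_{name}"] = mus + cas + rng.poisson(mu)
    table = pd.DataFrame({"gene": genes, "chrom": config.chrom, "tss": tss,
                          "snp_informative": informative, **rows})
    return table, truth


def generate_peak_sets(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    schedule: np.ndarray | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Accessibility peak sets accruing monotonically over pseudo-time.

    A baseline peak set (first timepoint) is drawn uniformly; new peaks are
    assigned to spatial clusters and appear cumulatively following
    ``schedule`` — an (n_clusters, n_timepoints) array of fractions of each
    cluster's final new peaks present at each timepoint (monotone, last
    column 1).  Default schedule is linear in time.  Also returns a bedGraph
    signal frame consistent with the final peak set (constant ``peak_height``
    over every peak present at the last timepoint).
    """
    rng = np.random.default_rng(config.seed + 2)
    if truth is None or truth.cluster_id is None:
        truth = plant_structure(config, np.random.default_rng(config.seed))
    tp = list(config.timepoints)
    n_t = len(tp)
    kk = config.n_clusters
    if schedule is None:
        schedule = np.tile(np.linspace(0, 1, n_t), (kk, 1))
    schedule = np.asarray(schedule, dtype=float)
    res = config.resolution

    def draw_peaks(n_peaks: int, taken: set[int]) -> pd.DataFrame:
        starts = []
        while len(starts) < n_peaks:
            s = int(rng.integers(0, config.chrom_length - config.peak_width))
            key = s // (2 * config.peak_width)
            if key in taken:
                continue
            taken.add(key)
            starts.append(s)
        starts = np.sort(np.array(starts))
        return pd.DataFrame({"chrom": config.chrom, "start": starts,
                             "end": starts + config.peak_width})

    taken: set[int] = set()
    baseline = draw_peaks(config.n_baseline_peaks, taken)
    new = draw_peaks(config.n_new_peaks, taken)
    mid_bins = np.minimum((new["start"] + config.peak_width // 2) // res,
                          len(truth.cluster_id) - 1)
    new_cluster = truth.cluster_id[mid_bins]
    peak_sets: dict[str, pd.DataFrame] = {}
    for t, name in enumerate(tp):
        frames = [baseline]
        for c in range(1, kk + 1):
            in_c = new[new_cluster == c]
            take = int(np.floor(schedule[c - 1, t] * len(in_c)))
            frames.append(in_c.iloc[:take])
        peaks = pd.concat(frames).sort_values("start").reset_index(drop=True)
        peak_sets[name] = peaks
    final = peak_sets[tp[-1]]
    signal = pd.DataFrame({"chrom": final["chrom"], "start": final["start"],
                           "end": final["end"], "value": config.peak_height})
    return peak_sets, signal


def planted_correlation_matrix(
    n_bins: int = 240,
    k: int = 12,
    n_archetypes: int = 5,
    contrast: float = 0.5,
    self_boost: float = 0.4,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block correlation matrix with k planted clusters from few archetypes.

    Bins are split into ``k`` contiguous blocks; each block is assigned one
    of ``n_archetypes`` interaction archetypes (cycling).  A bin pair
    correlates at +contrast when the archetypes match and -contrast
    otherwise, with an extra ``self_boost`` for pairs in the same cluster
    (contiguous spatial clusters are more self-correlated than their
    archetype at large), plus Gaussian noise; clipped to [-1, 1], zero
    diagonal.  Returns (matrix, cluster_truth 1..k, archetype_truth 1..n).
    """
    rng = np.random.default_rng(seed)
    block = np.array_split(np.arange(n_bins), k)
    cluster = np.empty(n_bins, dtype=int)
    for c, idx in enumerate(block):
        cluster[idx] = c + 1
    archetype = ((cluster - 1) % n_archetypes) + 1
    same = np.equal.outer(archetype, archetype)
    same_cluster = np.equal.outer(cluster, cluster)
    corr = (np.where(same, contrast, -contrast)
            + np.where(same_cluster, self_boost, 0.0)
            + rng.normal(0, noise_sd, (n_bins, n_bins)))
    corr = np.clip((corr + corr.T) / 2, -1, 1)
    np.fill_diagonal(corr, 0.0)
    return corr, cluster, archetype


def make_worked_fixture(seed: int = 23) -> dict:
    """Small deterministic end-to-end dataset (200 bins, 100 genes).

    Bundles allelic gene counts, peak sets, a signal track and a planted
    spatial clustering on a 20-Mb chromosome; the default seed is fixed so
    the bundled fixture exercises every stage (non-empty escapee set after
    the expression filter).  Regeneration with the same seed is
    byte-identical.  Expected outputs for every stage live in the
    repository's brute-force manifest (tests/fixtures/worked_manifest.json),
    computed once by an independent enumeration script.
    """
    config = SimulationConfig(
        seed=seed,
        chrom="chrS",
        chrom_length=20_000_000,
        resolution=100_000,
        megadomain_boundary=10_000_000,
        compartment_segment_mb=(1.0, 3.0),
        tad_size_mb=(0.3, 0.8),
        depth=2_000_000.0,
        masked_fraction=0.05,
        n_genes=100,
        gene_depth=150.0,
        n_clusters=4,
        n_baseline_peaks=40,
        n_new_peaks=80,
    )
    truth = plant_structure(config)
    genes, gene_truth = generate_allelic_counts(config)
    peaks, signal = generate_peak_sets(config, truth=truth)
    mapp = np.where(truth.masked, 0.3, 1.0)
    bins = BinTable.from_resolution(config.chrom, config.chrom_length,
                                    config.resolution, mappability=mapp)
    clustering = SpatialClustering(cluster_id=np.where(truth.masked, -1, truth.cluster_id),
                                   k=config.n_clusters)
    return {
        "config": config,
        "truth": truth,
        "gene_truth": gene_truth,
        "bins": bins,
        "genes": genes,
        "peak_sets": peaks,
        "signal": signal,
        "clustering": clustering,
    }
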