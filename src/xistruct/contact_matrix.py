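"""Allele-resolved intra-chromosomal Hi-C contact matrices.

The central container is :class:`ContactMatrix`: a dense symmetric matrix of
contact values over a :class:`BinTable` of equal-width genomic bins, carrying a
``state`` tag (``raw`` counts, ICE-``balanced``, or distance-normalized
``observed_over_expected``).  Masked bins (low mappability, no restriction
sites, or low counts) are represented by NaN rows/columns and never contribute
to decay profiles, row sums or balancing.

On-disk format is plain text: a TSV triplet ``bin_i<TAB>bin_j<TAB>count``
(optionally gzipped) plus a BED-like bin table with ``mappability`` and
``n_re_sites`` columns.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "BinTable",
    "ContactMatrix",
    "DecayProfile",
    "read_contacts",
    "write_contacts",
    "read_bins",
    "write_bins",
    "first_max_threshold",
    "filter_bins",
    "ice_balance",
    "observed_over_expected",
    "mix_matrices",
]

RAW = "raw"
BALANCED = "balanced"
OE = "observed_over_expected"

_BIN_COLUMNS = ["chrom", "start", "end", "mappability", "n_re_sites", "masked"]


@dataclass
class BinTable:
    """Equal-width genomic bins for one chromosome.

    Bins are contiguous, sorted and non-overlapping; all bins share the
    resolution except possibly the last (chromosome remainder).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col, default in (("mappability", 1.0), ("n_re_sites", 1), ("masked", False)):
            if col not in self.df.columns:
                self.df[col] = default
        self.df = self.df[_BIN_COLUMNS].reset_index(drop=True)
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        if len(starts) > 1 and not np.array_equal(starts[1:], ends[:-1]):
            raise ValueError("bins must be contiguous and sorted")
        widths = ends - starts
        if len(widths) > 1 and not (widths[:-1] == widths[0]).all():
            raise ValueError("all bins but the last must have equal width")

    @classmethod
    def from_resolution(
        cls,
        chrom: str,
        length: int,
        resolution: int,
        mappability: np.ndarray | None = None,
        n_re_sites: np.ndarray | None = None,
    ) -> "BinTable":
        starts = np.arange(0, length, resolution, dtype=np.int64)
        ends = np.minimum(starts + resolution, length)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        if mappability is not None:
            df["mappability"] = np.asarray(mappability, dtype=float)
        if n_re_sites is not None:
            df["n_re_sites"] = np.asarray(n_re_sites, dtype=int)
        return cls(df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> str:
        return str(self.df["chrom"].iloc[0])

    @property
    def resolution(self) -> int:
        return int(self.df["end"].iloc[0] - self.df["start"].iloc[0])

    @property
    def masked(self) -> np.ndarray:
        return self.df["masked"].to_numpy(dtype=bool)

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy(dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy(dtype=np.int64)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def with_masked(self, masked: np.ndarray) -> "BinTable":
        df = self.df.copy()
        df["masked"] = np.asarray(masked, dtype=bool)
        return BinTable(df)

    def bin_of(self, pos: np.ndarray | int) -> np.ndarray | int:
        """Bin index containing base-pair position(s) (0-based half-open)."""
        pos = np.asarray(pos)
        idx = np.minimum(pos // self.resolution, self.n_bins - 1)
        return idx if idx.ndim else int(idx)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinTable) and self.df.equals(other.df)


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix over a :class:`BinTable`."""

    bins: BinTable
    values: np.ndarray
    state: str = RAW
    allele: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.bins.n_bins
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), rtol=1e-10, atol=1e-8
        ):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def resolution(self) -> int:
        return self.bins.resolution

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.bins.masked

    def row_sums(self) -> np.ndarray:
        """Per-bin total contacts over unmasked partners (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nansum(np.where(np.isnan(self.values), 0.0, self.values), axis=0)

    def apply_mask(self, masked: np.ndarray) -> "ContactMatrix":
        """Return a copy with `masked` bins flagged and their rows/cols set NaN."""
        values = self.values.copy()
        masked = np.asarray(masked, dtype=bool)
        values[masked, :] = np.nan
        values[:, masked] = np.nan
        return ContactMatrix(self.bins.with_masked(masked), values, self.state, self.allele)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            BinTable(self.bins.df.copy()), self.values.copy(), self.state, self.allele
        )


@dataclass
class DecayProfile:
    """Mean interaction value per genomic distance (in bins), unmasked pairs only."""

    values: np.ndarray
    resolution: int = 0

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# I/O


def read_bins(path) -> BinTable:
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns:  # headerless BED3+ fallback
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "mappability", "n_re_sites"],
        )
    return BinTable(df)


def write_bins(bins: BinTable, path) -> None:
    bins.df.to_csv(path, sep="\t", index=False)


def read_contacts(path, bins_path=None, bins: BinTable | None = None, allele: str = "") -> ContactMatrix:
    """Read a raw contact matrix from a TSV triplet file.

    Records are ``bin_i  bin_j  count``; duplicate and transposed records are
    summed once into the symmetric matrix.
    """
    if bins is None:
        if bins_path is None:
            raise ValueError("either bins or bins_path is required")
        bins = read_bins(bins_path)
    n = bins.n_bins
    try:
        trip = pd.read_csv(path, sep="\t", header=None, names=["bin1", "bin2", "count"],
                           comment="#")
    except pd.errors.EmptyDataError:
        trip = pd.DataFrame({"bin1": [], "bin2": [], "count": []})
    values = np.zeros((n, n))
    if len(trip):
        i = trip["bin1"].to_numpy(dtype=np.int64)
        j = trip["bin2"].to_numpy(dtype=np.int64)
        c = trip["count"].to_numpy(dtype=float)
        if (i < 0).any() or (j < 0).any() or (i >= n).any() or (j >= n).any():
            raise ValueError("bin index out of range")
        if (c < 0).any():
            raise ValueError("negative counts")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        np.add.at(values, (lo, hi), c)
        upper = np.triu(values, 1)
        values = values + upper.T
    return ContactMatrix(bins, values, RAW, allele)


def write_contacts(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) of non-zero unmasked entries."""
    i, j = np.triu_indices(matrix.n_bins)
    v = matrix.values[i, j]
    keep = np.isfinite(v) & (v != 0)
    pd.DataFrame({"bin1": i[keep], "bin2": j[keep], "count": v[keep]}).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Bin filtering


def first_max_threshold(row_sums: np.ndarray) -> float:
    """Low-count threshold: position of the lowest-x local maximum of a KDE.

    A Gaussian kernel density (Silverman bandwidth) of the positive per-bin
    totals is evaluated on a 512-point grid spanning the data range; the
    returned threshold is the x-coordinate of the leftmost grid point that
    exceeds both neighbours.  Bins with row sum strictly below it are treated
    as low-count.
    """
    x = np.asarray(row_sums, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size == 0:
        raise ValueError("all-zero or empty row sums")
    if np.ptp(x) == 0:
        return float(x[0])
    if x.size < 10:
        raise ValueError("need at least 10 positive row sums")
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:  # monotone density: fall back to the global maximum
        return float(grid[np.argmax(dens)])
    return float(grid[peaks[0]])


def filter_bins(matrix: ContactMatrix, mappability_min: float = 0.5) -> ContactMatrix:
    """Mask bins with low mappability, no restriction sites, or low counts.

    A bin is masked when ``mappability < mappability_min`` OR
    ``n_re_sites == 0`` OR its total contact count falls strictly below the
    ``first_max`` KDE threshold of the row-sum distribution.  Returns a new
    matrix whose bin table carries the flags and whose masked rows/columns are
    NaN.
    """
    mapp = matrix.bins.df["mappability"].to_numpy(dtype=float)
    re_sites = matrix.bins.df["n_re_sites"].to_numpy(dtype=int)
    masked = (mapp < mappability_min) | (re_sites == 0)
    row_sums = matrix.row_sums()
    candidate = row_sums[~masked]
    if (candidate > 0).sum() >= 10 and np.ptp(candidate[candidate > 0]) > 0:
        thr = first_max_threshold(candidate)
        masked |= row_sums < thr
    return matrix.apply_mask(masked | matrix.bins.masked)


# ---------------------------------------------------------------------------
# Normalizations


def ice_balance(matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200) -> ContactMatrix:
    """Iterative correction: rescale rows/columns until unmasked row sums agree.

    The total unmasked signal is preserved (up to float rounding).  Unmasked
    rows that sum to zero are auto-masked with a warning.
    """
    out = matrix.copy()
    masked = out.bins.masked.copy()
    vals = np.where(np.isnan(out.values), 0.0, out.values)
    zero_rows = (~masked) & (vals.sum(axis=0) == 0)
    if zero_rows.any():
        warnings.warn(f"auto-masking {int(zero_rows.sum())} all-zero unmasked bins")
        masked |= zero_rows
    keep = ~masked
    sub = vals[np.ix_(keep, keep)]
    total = sub.sum()
    bias = np.ones(sub.shape[0])
    converged = False
    for _ in range(max_iter):
        s = sub.sum(axis=0)
        s = s / s.mean()
        sub = sub / np.outer(s, s)
        bias *= s
        if np.abs(s - 1).max() < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"ICE did not converge in {max_iter} iterations")
    if sub.sum() > 0:
        sub *= total / sub.sum()
    values = np.full_like(out.values, np.nan)
    values[np.ix_(keep, keep)] = sub
    return ContactMatrix(out.bins.with_masked(masked), values, BALANCED, out.allele)


def expected_decay(matrix: ContactMatrix) -> DecayProfile:
    """Mean interaction value at each bin distance, over unmasked pairs only."""
    n = matrix.n_bins
    keep = matrix.unmasked
    vals = matrix.values
    decay = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(vals, offset=d)
        ok = keep[: n - d] & keep[d:]
        if ok.any():
            v = diag[ok]
            v = v[np.isfinite(v)]
            if v.size:
                decay[d] = v.mean()
    return DecayProfile(decay, matrix.resolution)


def observed_over_expected(matrix: ContactMatrix) -> tuple[ContactMatrix, DecayProfile]:
    """Divide each entry by the mean value at its genomic distance.

    Distance classes whose mean is zero (or has no unmasked pairs) yield NaN.
    """
    decay = expected_decay(matrix)
    n = matrix.n_bins
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = decay.values[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, matrix.values / denom, np.nan)
    out = ContactMatrix(matrix.bins, oe, OE, matrix.allele)
    return out, decay


def mix_matrices(m_a: ContactMatrix, m_b: ContactMatrix, ratio: float) -> ContactMatrix:
    """In-silico mixture ``(1-ratio)*m_a + ratio*m_b`` after depth matching.

    Both inputs are scaled to equal total unmasked signal first, so ``ratio``
    reads as a cell fraction rather than a read fraction.
    """
    if not (0 <= ratio <= 1):
        raise ValueError("ratio must be in [0, 1]")
    if m_a.bins != m_b.bins:
        raise ValueError("bin tables differ")
    if m_a.state != m_b.state:
        raise ValueError("matrix states differ")

    def _tot(m: ContactMatrix) -> float:
        return float(np.nansum(np.where(np.isnan(m.values), 0.0, m.values)))

    ta, tb = _tot(m_a), _tot(m_b)
    target = (ta + tb) / 2
    va = m_a.values * (target / ta if ta > 0 else 1.0)
    vb = m_b.values * (target / tb if tb > 0 else 1.0)
    return ContactMatrix(m_a.bins, (1 - ratio) * va + ratio * vb, m_a.state, m_a.allele)
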