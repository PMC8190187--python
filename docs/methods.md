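# Methods

This note documents the models, parameter choices and numerical decisions
behind `xistruct`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model

Contact matrices are dense, symmetric, per-allele and intra-chromosomal,
over a table of equal-width bins (0-based, half-open coordinates; the
resolution is a property of the bin table, never inferred from data). A
matrix carries one of three states: `raw` (integer counts),
`balanced` (ICE), or `observed_over_expected`. Missing values are explicit
NaN throughout — masked bins are NaN rows/columns and never contribute to
row sums, decay profiles, balancing or correlation matrices. On-disk formats
are plain text: a `bin_i  bin_j  count` triplet TSV (upper triangle;
transposed/duplicate records are summed once) and a BED-like bin table with
`mappability` and `n_re_sites` columns.

## Bin filtering

A bin is masked when any of three rules fires: mappability < 0.5, zero
restriction-enzyme sites, or a total contact count below the *first-max*
threshold — the x-position of the leftmost local maximum of a Gaussian
kernel density estimate (Silverman bandwidth, 512-point grid over the data
range) of the positive row sums. The heuristic assumes the row-sum
distribution separates a low-count failure mode from the main mass; on
degenerate inputs (constant vector) the constant is returned, and a
monotone density falls back to the global maximum. Whether the published
heuristic returns the mode's position or its density value is ambiguous;
we use the position, which is the only choice on the scale of counts.

## Normalization

Balancing is ICE (iterative correction): rows and columns of the unmasked
submatrix are rescaled until row sums agree to a relative tolerance
(default 1e-5, 200 iterations), preserving total signal. All-zero unmasked
rows are auto-masked with a warning. Observed/expected divides each entry
by the mean value at its bin distance, computed over unmasked pairs only;
distance classes with zero mean yield NaN. O/E is idempotent and ICE is
idempotent up to tolerance; both properties are tested.

In-silico mixing first scales both inputs to equal total unmasked signal,
then combines entrywise as `(1−r)·A + r·B`; the depth matching makes `r` a
cell fraction rather than a read fraction, so any per-bin linear statistic
of the mixture is the same mixture of the statistics.

## Compartments

Because the Xi's two mega-domains dominate the leading eigenvector of a
whole-chromosome correlation matrix, compartment calling splits the matrix
at the mega-domain boundary (default 75.6 Mb) and processes each arm
independently: O/E **within the arm** (the whole-chromosome decay is
distorted by damped inter-mega-domain pairs — using it leaks an arm-scale
gradient into PC1), Pearson correlation over unmasked bins, leading
eigenvector by dense symmetric eigendecomposition (largest algebraic
eigenvalue). Each arm's eigenvector is oriented by its Pearson correlation
with a per-bin GC track (A = GC-rich = positive); without a GC track the
sign is fixed deterministically (non-negative sum) but carries no meaning.

Calibration fits a two-component unequal-variance Gaussian mixture to PC1
(EM, 10 restarts, tolerance 1e-6, seeded) after symmetrically trimming the
extreme 5% of values (2.5% per tail) — the trim affects fitting only; every
bin receives a calibrated value. The centring point is the density
intersection `w₁φ₁(x) = w₂φ₂(x)` between the two component means, located
by a 2048-point sign-change scan plus Brent bisection (xtol 1e-12); if no
crossing exists between the means (extreme weight imbalance) the point of
closest approach is used, and coincident means fall back to the trimmed
median with a warning. After centring, positive values are divided by the
maximum positive value and negative values by |minimum|, giving [−1, +1]
with labels A (> 0) and B (< 0). Calibration is monotone within each sign
class.

Segment counting merges runs of consecutive same-label unmasked bins and
drops segments shorter than 300 kb without re-merging across the gap.
Masked bins break runs (interval merging of adjacent features does not
bridge gaps). Saddle grids use 50 equal-count rank categories of PC1 (ties
broken by bin index), mean log₂ O/E per category pair, diagonal excluded,
symmetrized. Compartment strength takes the top/bottom 20% of bins by PC1
and reports the median log₂ O/E of A–A, B–B and A–B pairs; the overall
strength is `(AA + BB)/2 − AB` — the source analysis prints strength values
without stating the combination rule, so this symmetric contrast is our
choice and is stated wherever the number is reported.

## Subcompartments

The clustering matrix is built raw → O/E → ICE → clip entries above the
90th percentile → Pearson correlation → zero diagonal → linear rescale of
[5th, 95th] percentiles onto [−1, +1] with clipping outside. Features for
k-means are the 12 leading eigenvectors by algebraic eigenvalue, each
multiplied by its (signed) eigenvalue; k-means uses k-means++ with 10
restarts and a seed, keeping the best inertia. Cluster labels are 1..k with
−1 marking masked bins (integer arrays cannot carry NaN).

Cross-sample label transfer re-clusters each sample and aligns labels to a
reference clustering by maximum-overlap optimal assignment (Hungarian
algorithm on the k×k contingency table); the alignment equals exhaustive
search over all k! bijections (tested for k ≤ 6) and never decreases
overlap.

Consolidation into the five named subcompartments is deliberately concrete
where the source description is qualitative: the k rows of the
cluster-interaction matrix (mean O/E between clusters, diagonal pairs
excluded) are hierarchically clustered (average linkage, Euclidean) into 5
groups, ordered by descending mean calibrated PC1 of member bins (ties →
smaller lowest cluster id), and named A1, A2, AB, B1, B2 in that order.

Inter-mega-domain fractions restrict to unmasked pairs more than 8.2 Mb
apart on opposite sides of the split point, call the top 20% by balanced
value "strong" (threshold = 0.8 quantile; ties at the threshold are
included, so a constant matrix gives every cluster a fraction of 1), and
report per cluster the strong share among qualifying pairs touching it;
clusters with no qualifying pairs are NaN, not 0.

## TADs and domain scores

The insulation score of bin b is the mean contact value in the
`window × window` square upstream×downstream of b (default 10 bins,
i.e. 500 kb at 50-kb resolution — the window is exposed as a parameter),
log₂-normalized to the mean over eligible bins, then smoothed by a 7-bin
centred moving average that shrinks at edges and NaN gaps. Borders are
strict local minima of the smoothed score (nearest finite neighbours;
plateaus take the leftmost bin) below −0.086. TADs tile the contiguous
unmasked stretches between consecutive borders (the border bin starts the
downstream TAD); mask gaps break TADs — domain scores across unmappable
stretches are not meaningful — and fragments under 3 bins are dropped.

The domain score of TAD T is `sum(V[T,T]) / sum(V[T,:])` on the balanced
matrix with the diagonal excluded: the share of T's cis contacts that stay
inside T. On a uniform n-bin matrix a k-bin TAD scores k(k−1)/(k(n−1)) ≈
k/n, the score is invariant to global scaling and bounded in [0, 1]. The
relative domain score across a series is `(mid − start)/(end − start)`,
with |end − start| < 0.01 reported missing. Early/late classification runs
1-D k-means (k=2, seeded); "early" is the cluster with the larger centre,
and the fraction of TADs with relative score > 0.2 is reported alongside as
a model-free cross-check (the k-means labels are authoritative). Per-TAD
omics trajectories use the same relative transform, excluding TADs with an
end-state count below a minimum (default 15 peaks) or a flat trajectory.

## Allelic statistics

Read assignment is a pure decision rule over per-genome (MAPQ, alignment
score) pairs: unmapped if both MAPQ are 0, otherwise the strictly greater
alignment score wins, with equality ambiguous. The allelic ratio is
`mus/(mus+cas)`, NaN at zero depth. The gene funnel keeps SNP-informative
genes, then genes with reference-state cas expression at or above the 25th
percentile (linear-interpolation quantile; ties kept, since only genes
*below* the percentile are removed). The percentile is computed on the
reference (inactive-state) sample, one concrete reading of an underspecified
rule. All classification thresholds are strict as printed: escapee and
reactivated at ratio > 0.14, biallelic at 0.4 < ratio < 0.6 at both
endpoint samples; reactivation analyses are restricted to
biallelic-endpoint genes. Differential peaks are peaks with zero overlap
(≥1 bp disqualifies) with any baseline peak, assigned to clusters by
midpoint; relative differential peak values divide each cluster's count by
its end-sample count, so baseline = 0 and endpoint = 1 by construction.
Promoter accessibility sums value × overlap over ±2 kb around the TSS.
Genes are assigned to spatial clusters by their TSS bin.

## Synthetic generators

The expected contact matrix is analytic:

    E(i,j) ∝ (1+|i−j|)^(−α) · C(i,j) · T(i,j) · M(i,j)

with α = 1 (typical intra-chromosomal decay), C = 1±contrast for
same/different compartment labels (default contrast 0.3), T the intra-TAD
fold (default 2×, scaled per pseudo-timepoint by an attenuation schedule —
the inactive-X-like allele starts TAD-free and regains full TADs), and M a
cross-mega-domain damping factor (default 0.4, inactive allele only).
Entries are scaled to a total depth (default 5×10⁶ contacts over 1700
100-kb bins ≈ a deep allele-resolved chromosome X map) and Poisson-sampled;
5% of bins are masked at random. Compartment segments are 2–8 Mb, TADs
0.4–1.6 Mb and nested inside compartment segments so recovery tests are not
confounded. A GC track (0.45 in A, 0.40 in B, σ 0.005) supports eigenvector
orientation.

Expression counts follow the standard allele-specific model: per gene a
total ~ NegBinom(μ, dispersion 0.1) with μ lognormal around 200 reads, split
Binomial(total, r) between alleles so the realized ratio concentrates at the
planted ratio r. Escapees (10% of informative genes) hold r = 0.3
throughout; silenced genes sit at r = 0.02 until their planted reactivation
timepoint and at 0.5 from then on; all genes are biallelic at the two
endpoint samples; ~31% of genes are SNP-uninformative (zero allelic
counts), mirroring the 806→558 informative fraction of a real X-linked gene
set. Peak sets accrue monotonically per cluster following a schedule, never
losing peaks.

What the generators do **not** emulate: loop/stripe structures, covariate
biases correlated along the genome (GC/mappability gradients —
normalization is tested only against multiplicative row biases),
trans-chromosomal contacts, batch effects in expression, and read-level
artifacts. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise models, not robustness to every artifact
of real sequencing data.

## Verification scales and numerical choices

Recovery tests and the acceptance script run at deliberate problem sizes:
1700 bins at 100 kb for compartments (the full chromosome X scale),
420–500 bins at 50 kb for TAD calling and mixing (~20 planted borders), 240
bins for subcompartment clustering, and the bundled 200-bin/100-gene worked
fixture for the allelic pipeline, whose expected outputs were computed once
by an independent brute-force enumeration script
(`scripts/build_fixture_manifest.py`) and frozen into
`tests/fixtures/worked_manifest.json`. The fixture's default seed is fixed
so that the small gene set is non-degenerate (escapees survive the
expression filter).

The −0.086 border cutoff is tied to the insulation-score scale of the real
data; on synthetic matrices it is rescaled by the ratio of the observed
smoothed-score IQR to 0.30, the IQR produced by the generator's reference
condition (2× enrichment at the defaults), so the cutoff sits at the same
relative depth of the score distribution. Borders closer to a chromosome
end than window + smoothing reach (14 bins) cannot form a local minimum and
are excluded from recovery accounting.

## Known limitations

- Balancing is plain ICE; covariate-regression normalization (mappability,
  GC, SNP density as explicit model terms) is out of scope, so residual
  covariate structure in real data would reach the downstream stages.
- The consolidation rule for subcompartments is one concrete choice among
  several defensible ones; on real data the 12→5 grouping should be
  inspected, not trusted blindly.
- The early/late TAD split assumes the relative-score distribution is
  two-moded; k-means will split a unimodal distribution anyway (the > 0.2
  cross-check fraction is reported to catch this).
- Loop calling, motif analysis, differential expression and visualization
  layouts are intentionally absent; the package emits the quantities those
  tools consume.
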