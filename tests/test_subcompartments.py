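"""Spatial clustering, label alignment, consolidation and cluster statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from xistruct.contact_matrix import OE, RAW, BinTable, ContactMatrix
from xistruct.simulate import planted_correlation_matrix
from xistruct.subcompartments import (
    SUBCOMPARTMENT_NAMES,
    SpatialClustering,
    align_cluster_labels,
    annotate_clusters_with_track,
    build_correlation_matrix,
    cluster_interaction_matrix,
    cluster_spatial,
    consolidate_subcompartments,
    inter_megadomain_fraction,
)
from conftest import make_matrix


def two_block_raw_matrix(n=60, seed=0):
    rng = np.random.default_rng(seed)
    lab = (np.arange(n) >= n // 2).astype(int)
    same = np.equal.outer(lab, lab)
    dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = (1.0 + dist) ** -0.8 * np.where(same, 1.6, 0.4) * 2000
    up = np.triu(rng.poisson(e))
    return make_matrix((up + np.triu(up, 1).T).astype(float)), lab


class TestCorrelationMatrix:
    def test_two_block_structure_near_plus_one_within_blocks(self):
        m, lab = two_block_raw_matrix()
        corr = build_correlation_matrix(m)
        same = np.equal.outer(lab, lab)
        off = ~np.eye(len(lab), dtype=bool)
        assert np.nanmean(corr[same & off]) > 0.5
        assert np.nanmean(corr[~same]) < -0.5

    def test_rescale_maps_percentiles_to_unit_range(self):
        m, _ = two_block_raw_matrix(seed=1)
        corr = build_correlation_matrix(m)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        off = off[np.isfinite(off)]
        assert off.min() == -1.0 and off.max() == 1.0
        # ~5% of entries pinned at each end by the clipping
        assert 0.01 < (off == -1.0).mean() < 0.15
        assert 0.01 < (off == 1.0).mean() < 0.15

    def test_diagonal_is_zero(self):
        m, _ = two_block_raw_matrix(seed=2)
        corr = build_correlation_matrix(m)
        np.testing.assert_array_equal(np.diag(corr), 0.0)


class TestClusterSpatial:
    def test_twelve_planted_blocks_recovered(self):
        corr, truth, _ = planted_correlation_matrix(n_bins=240, k=12, seed=3)
        res = cluster_spatial(corr, k=12, seed=0)
        assert adjusted_rand_score(truth, res.cluster_id) == 1.0

    def test_two_block_matrix_k2_exact(self):
        m, lab = two_block_raw_matrix(seed=4)
        corr = build_correlation_matrix(m)
        res = cluster_spatial(corr, k=2, n_eig=2, seed=0)
        assert adjusted_rand_score(lab, res.cluster_id) == 1.0

    def test_invariant_to_bin_permutation(self):
        corr, truth, _ = planted_correlation_matrix(n_bins=120, k=6, seed=5)
        res = cluster_spatial(corr, k=6, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(120)
        res_p = cluster_spatial(corr[np.ix_(perm, perm)], k=6, seed=0)
        unpermuted = np.empty(120, dtype=int)
        unpermuted[perm] = res_p.cluster_id
        assert adjusted_rand_score(res.cluster_id, unpermuted) == 1.0

    def test_k_larger_than_bins_rejected(self):
        corr, _, _ = planted_correlation_matrix(n_bins=20, k=4, seed=0)
        with pytest.raises(ValueError):
            cluster_spatial(corr, k=30)

    def test_deterministic_given_seed(self):
        corr, _, _ = planted_correlation_matrix(n_bins=120, k=6, seed=6)
        a = cluster_spatial(corr, k=6, seed=7)
        b = cluster_spatial(corr, k=6, seed=7)
        np.testing.assert_array_equal(a.cluster_id, b.cluster_id)


class TestAlignLabels:
    def test_identical_clusterings_identity(self):
        labels = np.repeat(np.arange(1, 5), 10)
        a = SpatialClustering(cluster_id=labels.copy(), k=4)
        out = align_cluster_labels(a, SpatialClustering(cluster_id=labels.copy(), k=4))
        np.testing.assert_array_equal(out.cluster_id, labels)

    def test_known_permutation_recovered(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(1, 7, 200)
        perm = {1: 4, 2: 6, 3: 1, 4: 2, 5: 3, 6: 5}
        scrambled = np.array([perm[x] for x in ref])
        out = align_cluster_labels(SpatialClustering(cluster_id=scrambled, k=6),
                                   SpatialClustering(cluster_id=ref, k=6))
        np.testing.assert_array_equal(out.cluster_id, ref)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_alignment_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        k = 5
        ref = rng.integers(1, k + 1, 150)
        perm = dict(zip(range(1, k + 1), rng.permutation(np.arange(1, k + 1))))
        labels = np.array([perm[x] for x in ref])
        noise = rng.random(150) < 0.1
        labels[noise] = rng.integers(1, k + 1, noise.sum())
        out = align_cluster_labels(SpatialClustering(cluster_id=labels, k=k),
                                   SpatialClustering(cluster_id=ref, k=k))
        # brute-force oracle over all k! bijections
        best, best_overlap = None, -1
        for p in itertools.permutations(range(1, k + 1)):
            mapping = dict(zip(range(1, k + 1), p))
            mapped = np.array([mapping[x] for x in labels])
            overlap = (mapped == ref).sum()
            if overlap > best_overlap:
                best, best_overlap = mapped, overlap
        assert (out.cluster_id == ref).sum() == best_overlap

    def test_alignment_never_decreases_overlap(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(1, 5, 100)
        labels = rng.integers(1, 5, 100)
        out = align_cluster_labels(SpatialClustering(cluster_id=labels, k=4),
                                   SpatialClustering(cluster_id=ref, k=4))
        assert (out.cluster_id == ref).sum() >= (labels == ref).sum()


class TestClusterInteractions:
    def test_uniform_matrix_all_entries_equal(self):
        m = make_matrix(np.ones((40, 40)), state=OE)
        cl = SpatialClustering(cluster_id=np.repeat([1, 2, 3, 4], 10), k=4)
        out = cluster_interaction_matrix(m, cl)
        np.testing.assert_allclose(out, 1.0)

    def test_planted_blocks_show_diagonal_dominance_and_symmetry(self):
        n = 60
        cl_id = np.repeat([1, 2, 3], 20)
        same = np.equal.outer(cl_id, cl_id)
        m = make_matrix(np.where(same, 2.0, 0.5), state=OE)
        out = cluster_interaction_matrix(m, SpatialClustering(cluster_id=cl_id, k=3))
        assert (np.diag(out) > out[~np.eye(3, dtype=bool)].max()).all()
        np.testing.assert_allclose(out, out.T)

    def test_empty_cluster_rejected(self):
        m = make_matrix(np.ones((10, 10)), state=OE)
        cl = SpatialClustering(cluster_id=np.ones(10, dtype=int), k=2)
        with pytest.raises(ValueError):
            cluster_interaction_matrix(m, cl)


class TestConsolidation:
    def _setup(self, seed=0):
        corr, cl_truth, arch = planted_correlation_matrix(n_bins=240, k=12, seed=seed)
        clustering = SpatialClustering(cluster_id=cl_truth, k=12)
        same_a = np.equal.outer(arch, arch)
        same_c = np.equal.outer(cl_truth, cl_truth)
        oe = np.where(same_a, 2.0, 0.5) + np.where(same_c, 0.8, 0.0)
        bins = BinTable.from_resolution("chrS", 240 * 100_000, 100_000)
        C = cluster_interaction_matrix(ContactMatrix(bins, oe, OE), clustering)
        pc1 = -arch.astype(float)  # archetype 1 = most A-like
        return clustering, C, pc1, cl_truth, arch

    def test_archetypes_recovered_exactly(self):
        clustering, C, pc1, cl_truth, arch = self._setup()
        cons = consolidate_subcompartments(clustering, C, pc1)
        for c in range(1, 13):
            expected = SUBCOMPARTMENT_NAMES[arch[cl_truth == c][0] - 1]
            assert cons.subcompartment_of_cluster[c] == expected

    def test_highest_mean_pc1_group_named_a1(self):
        clustering, C, pc1, cl_truth, arch = self._setup(seed=1)
        cons = consolidate_subcompartments(clustering, C, pc1)
        means = {name: pc1[cons.subcompartment == name].mean()
                 for name in SUBCOMPARTMENT_NAMES}
        order = sorted(means, key=means.get, reverse=True)
        assert order == list(SUBCOMPARTMENT_NAMES)

    def test_every_cluster_gets_exactly_one_subcompartment(self):
        clustering, C, pc1, *_ = self._setup(seed=2)
        cons = consolidate_subcompartments(clustering, C, pc1)
        assert set(cons.subcompartment_of_cluster) == set(range(1, 13))
        assert set(cons.subcompartment_of_cluster.values()) == set(SUBCOMPARTMENT_NAMES)

    def test_k_below_five_rejected(self):
        cl = SpatialClustering(cluster_id=np.repeat([1, 2, 3], 10), k=3)
        with pytest.raises(ValueError):
            consolidate_subcompartments(cl, np.ones((3, 3)), np.zeros(30))


class TestInterMegadomain:
    def _matrix(self, n=120, res=100_000):
        vals = np.ones((n, n))
        bins = BinTable.from_resolution("chrT", n * res, res)
        return ContactMatrix(bins, vals, "balanced")

    def test_all_equal_values_make_every_fraction_one(self):
        # every qualifying pair ties at the threshold and is included
        m = self._matrix()
        cl = SpatialClustering(cluster_id=np.repeat([1, 2], 60), k=2)
        out = inter_megadomain_fraction(m, cl, split_point=60 * 100_000,
                                        min_dist=2_000_000)
        assert out[1] == 1.0 and out[2] == 1.0

    def test_boosted_cluster_has_highest_fraction(self):
        m = self._matrix()
        cl_id = np.repeat([1, 2, 3, 4], 30)
        boost = np.ix_(cl_id == 2, np.arange(120) >= 60)
        vals = m.values.copy()
        vals[boost] *= 10
        vals = np.maximum(vals, vals.T)
        m = ContactMatrix(m.bins, vals, "balanced")
        cl = SpatialClustering(cluster_id=cl_id, k=4)
        out = inter_megadomain_fraction(m, cl, split_point=60 * 100_000,
                                        min_dist=2_000_000)
        assert out[2] == max(out.values())

    def test_cluster_without_qualifying_pairs_is_missing(self):
        m = self._matrix()
        cl_id = np.repeat([1, 2], 60)
        cl_id[:3] = 3  # cluster 3 sits far left; still crosses the split at long range
        cl_id[55:60] = 4  # cluster 4 near the split: all cross pairs too close
        cl = SpatialClustering(cluster_id=cl_id, k=4)
        out = inter_megadomain_fraction(m, cl, split_point=60 * 100_000,
                                        min_dist=7_000_000)
        assert np.isnan(out[4])

    def test_no_qualifying_pairs_rejected(self):
        m = self._matrix(n=20)
        cl = SpatialClustering(cluster_id=np.repeat([1, 2], 10), k=2)
        with pytest.raises(ValueError):
            inter_megadomain_fraction(m, cl, split_point=10 * 100_000,
                                      min_dist=8_200_000)


class TestAnnotate:
    def _clustering(self):
        return SpatialClustering(cluster_id=np.repeat([1, 2], 5), k=2)

    def _bins(self):
        return BinTable.from_resolution("chrT", 10 * 100_000, 100_000)

    def test_constant_track_groups_equal_p_one(self):
        track = pd.DataFrame({"chrom": "chrT", "start": [0], "end": [1_000_000],
                              "value": [2.5]})
        summary, pvals = annotate_clusters_with_track(self._clustering(), self._bins(), track)
        assert (summary["mean"] == 2.5).all()
        assert pvals.loc[1, 2] == 1.0

    def test_track_equal_to_cluster_id_separates_groups(self):
        track = pd.DataFrame({"chrom": "chrT",
                              "start": [0, 500_000],
                              "end": [500_000, 1_000_000],
                              "value": [1.0, 2.0]})
        summary, _ = annotate_clusters_with_track(self._clustering(), self._bins(), track)
        assert summary.set_index("group").loc[1, "mean"] == 1.0
        assert summary.set_index("group").loc[2, "mean"] == 2.0

    def test_half_overlapping_interval_contributes_half_weight(self):
        # bin 0 covered half by value 4 and half by value 0 -> weighted mean 2
        track = pd.DataFrame({"chrom": "chrT",
                              "start": [0, 50_000],
                              "end": [50_000, 100_000],
                              "value": [4.0, 0.0]})
        from xistruct.subcompartments import _bin_track_means

        means = _bin_track_means(self._bins(), track)
        assert means[0] == pytest.approx(2.0)

    def test_wrong_chromosome_rejected(self):
        track = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [100],
                              "value": [1.0]})
        with pytest.raises(ValueError):
            annotate_clusters_with_track(self._clustering(), self._bins(), track)
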