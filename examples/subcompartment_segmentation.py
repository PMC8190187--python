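"""Segment a chromosome into spatial clusters and five subcompartments.

Builds a planted correlation matrix whose 12 contiguous clusters draw their
long-range interaction profiles from 5 archetypes, clusters it with k-means
on eigenvalue-weighted eigenvectors, and consolidates the clusters into the
named subcompartments A1, A2, AB, B1, B2 ordered by compartment eigenvector.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import xistruct as xs
from xistruct.simulate import planted_correlation_matrix
from xistruct.subcompartments import SpatialClustering, cluster_interaction_matrix

corr, cluster_truth, archetype_truth = planted_correlation_matrix(
    n_bins=240, k=12, seed=1)
clustering = xs.cluster_spatial(corr, k=12, n_eig=12, restarts=10, seed=1)
print(f"adjusted Rand index vs planted clusters: "
      f"{adjusted_rand_score(cluster_truth, clustering.cluster_id):.3f}")

aligned = xs.align_cluster_labels(
    clustering, SpatialClustering(cluster_id=cluster_truth, k=12))
same_arch = np.equal.outer(archetype_truth, archetype_truth)
same_cluster = np.equal.outer(cluster_truth, cluster_truth)
oe = np.where(same_arch, 2.0, 0.5) + np.where(same_cluster, 0.8, 0.0)
bins = xs.BinTable.from_resolution("chrS", 240 * 100_000, 100_000)
interactions = cluster_interaction_matrix(
    xs.ContactMatrix(bins, oe, "observed_over_expected"), aligned)
consolidated = xs.consolidate_subcompartments(
    aligned, interactions, -archetype_truth.astype(float))
print("cluster -> subcompartment:", consolidated.subcompartment_of_cluster)
# clusters drawn from the same archetype receive the same subcompartment
# name; names run A1 (highest mean eigenvector, most open) to B2.
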