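import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spotmap import (
    NormalizedMatrix,
    SegmentedMap,
    cluster,
    cluster_summaries,
    normalize_by_gene_totals,
    pca_report,
    rgb_embedding,
)


def _seg(counts, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    return SegmentedMap(
        counts=pd.DataFrame(counts, columns=genes),
        unit_kind="bin",
        centroids=np.zeros((len(counts), 2)),
    )


def three_signature_seg(n_per=40, seed=0):
    """Three unit groups, each dominated by its own marker gene."""
    rng = np.random.default_rng(seed)
    blocks = []
    for i in range(3):
        lam = np.full(6, 2.0)
        lam[i] = 50.0
        blocks.append(rng.poisson(lam, (n_per, 6)))
    counts = np.vstack(blocks)
    truth = np.repeat([0, 1, 2], n_per)
    return _seg(counts), truth


class TestNormalize:
    def test_single_unit_nonzero_columns_become_one(self):
        from spotmap import qc_filter

        seg, _ = qc_filter(_seg([[4, 0, 9]]), min_reads_per_gene=1)
        norm = normalize_by_gene_totals(seg)
        np.testing.assert_allclose(norm.values.iloc[0].to_numpy(), [1.0, 1.0])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        norm = normalize_by_gene_totals(_seg(rng.integers(1, 20, (15, 5))))
        np.testing.assert_allclose(norm.values.sum(axis=0), 1.0)

    def test_proportional_columns_become_identical(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 30, 20)
        counts = np.column_stack([base, base * 10])
        norm = normalize_by_gene_totals(_seg(counts))
        np.testing.assert_allclose(
            norm.values.iloc[:, 0], norm.values.iloc[:, 1], atol=1e-12
        )

    def test_zero_total_gene_raises(self):
        with pytest.raises(ValueError, match="qc_filter"):
            normalize_by_gene_totals(_seg([[1, 0], [2, 0]]))


class TestPca:
    def test_planar_data_has_rank_two(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(size=(2, 6))
        coords = rng.normal(size=(30, 2))
        mat = NormalizedMatrix(
            pd.DataFrame(coords @ basis, columns=[f"g{i}" for i in range(6)]),
            "test", {},
        )
        rep = pca_report(mat, n_components=6)
        assert rep["variance_ratio"].iloc[2:].max() < 1e-9

    def test_variance_ratios_sum_to_one_and_nonincreasing(self):
        rng = np.random.default_rng(3)
        mat = NormalizedMatrix(
            pd.DataFrame(rng.normal(size=(40, 5))), "test", {}
        )
        vr = pca_report(mat, n_components=5)["variance_ratio"]
        assert vr.sum() == pytest.approx(1.0)
        assert (np.diff(vr) <= 1e-12).all()

    def test_pc1_matches_analytic_eigenvector(self):
        """2-gene toy with known covariance: PC1 equals the leading
        eigenvector of the 2×2 covariance, computed in closed form."""
        rng = np.random.default_rng(4)
        cov = np.array([[4.0, 1.5], [1.5, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=20_000)
        # closed-form leading eigenvector of [[a,b],[b,c]]
        emp = np.cov(x.T)
        a, b, c = emp[0, 0], emp[0, 1], emp[1, 1]
        lam = (a + c) / 2 + np.sqrt(((a - c) / 2) ** 2 + b**2)
        v = np.array([b, lam - a])
        v /= np.linalg.norm(v)
        mat = NormalizedMatrix(pd.DataFrame(x, columns=["g1", "g2"]), "t", {})
        pc1 = pca_report(mat, n_components=2)["loadings"].iloc[0].to_numpy()
        assert abs(np.dot(pc1, v)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_raises(self):
        mat = NormalizedMatrix(pd.DataFrame(np.ones((10, 3))), "t", {})
        with pytest.raises(ValueError):
            pca_report(mat)

    def test_scores_invariant_to_gene_order_up_to_sign(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        r1 = pca_report(NormalizedMatrix(df, "t", {}), 3)["scores"].to_numpy()
        r2 = pca_report(
            NormalizedMatrix(df[list("dcba")], "t", {}), 3
        )["scores"].to_numpy()
        for j in range(3):
            assert (np.allclose(r1[:, j], r2[:, j], atol=1e-9)
                    or np.allclose(r1[:, j], -r2[:, j], atol=1e-9))


class TestRgbEmbedding:
    @pytest.mark.parametrize("method", ["pca", "umap"])
    def test_channels_span_unit_interval(self, method):
        seg, _ = three_signature_seg()
        emb = rgb_embedding(normalize_by_gene_totals(seg), method, seed=0)
        np.testing.assert_allclose(emb.rgb.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(emb.rgb.max(axis=0), 1.0, atol=1e-12)

    def test_identical_profiles_identical_rgb(self):
        counts = np.tile([[5, 1, 1], [1, 5, 1], [1, 1, 5], [3, 3, 3]], (2, 1))
        emb = rgb_embedding(
            normalize_by_gene_totals(_seg(counts)), "pca", seed=0
        )
        np.testing.assert_allclose(emb.rgb[0], emb.rgb[4], atol=1e-9)

    def test_three_regions_separate_in_rgb(self):
        """Mean between-group RGB distance exceeds mean within-group."""
        seg, truth = three_signature_seg()
        emb = rgb_embedding(normalize_by_gene_totals(seg), "pca", seed=0)
        rgb = emb.rgb
        within, between = [], []
        for i in range(len(rgb)):
            for j in range(i + 1, len(rgb)):
                d = np.linalg.norm(rgb[i] - rgb[j])
                (within if truth[i] == truth[j] else between).append(d)
        assert np.mean(between) > np.mean(within)

    def test_too_few_units_raises(self):
        with pytest.raises(ValueError):
            rgb_embedding(
                normalize_by_gene_totals(_seg([[1, 2], [3, 4], [5, 6]])), "pca"
            )


class TestCluster:
    def test_kmeans_recovers_three_signatures_across_seeds(self):
        seg, truth = three_signature_seg()
        norm = normalize_by_gene_totals(seg)
        aris = [
            adjusted_rand_score(truth, cluster(norm, "kmeans", k=3, seed=s).labels)
            for s in range(10)
        ]
        assert min(aris) >= 0.9

    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.05, (20, 3)) + [1, 0, 0]
        b = rng.normal(0, 0.05, (20, 3)) + [0, 1, 0]
        mat = NormalizedMatrix(pd.DataFrame(np.vstack([a, b])), "t", {})
        labels = cluster(mat, "kmeans", k=2, seed=0).labels
        assert adjusted_rand_score([0] * 20 + [1] * 20, labels) == 1.0

    def test_hierarchical_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(7)
        mat = NormalizedMatrix(pd.DataFrame(rng.normal(size=(8, 3))), "t", {})
        labels = cluster(mat, "hierarchical", k=8).labels
        assert len(np.unique(labels)) == 8

    def test_order_permutation_gives_same_partition(self):
        seg, _ = three_signature_seg()
        norm = normalize_by_gene_totals(seg)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(norm.values))
        permuted = NormalizedMatrix(
            norm.values.iloc[perm].reset_index(drop=True), norm.method, {}
        )
        l1 = cluster(norm, "kmeans", k=3, seed=1).labels
        l2 = cluster(permuted, "kmeans", k=3, seed=1).labels
        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_dbscan_can_emit_noise(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 0.01, (30, 2)), [[5.0, 5.0]]])
        mat = NormalizedMatrix(pd.DataFrame(x), "t", {})
        labels = cluster(mat, "dbscan", eps=0.1, min_samples=5).labels
        assert -1 in labels

    def test_k_larger_than_units_raises(self):
        mat = NormalizedMatrix(pd.DataFrame(np.eye(3)), "t", {})
        with pytest.raises(ValueError):
            cluster(mat, "kmeans", k=5)


class TestClusterSummaries:
    def test_single_cluster_row_is_global_mean(self):
        seg, _ = three_signature_seg(n_per=5)
        from spotmap import ClusterAssignment

        assign = ClusterAssignment(np.zeros(15, int), "kmeans", {}, 0)
        means = cluster_summaries(assign, seg)
        np.testing.assert_allclose(
            means.loc[0], seg.counts.mean(axis=0), atol=1e-12
        )

    def test_singleton_cluster_row_is_unit_profile(self):
        seg, _ = three_signature_seg(n_per=4)
        from spotmap import ClusterAssignment

        labels = np.zeros(12, int)
        labels[5] = 1
        means = cluster_summaries(ClusterAssignment(labels, "kmeans", {}, 0), seg)
        np.testing.assert_allclose(
            means.loc[1], seg.counts.iloc[5], atol=1e-12
        )

    def test_planted_markers_top_their_cluster(self):
        seg, truth = three_signature_seg()
        from spotmap import ClusterAssignment

        means = cluster_summaries(
            ClusterAssignment(truth, "kmeans", {}, 0), seg
        )
        for i in range(3):
            assert means.loc[i].idxmax() == f"g{i}"
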