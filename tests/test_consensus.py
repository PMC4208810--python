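import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from icpipe import (
    CohortSpec,
    PipelineConfig,
    average_linkage_cluster,
    consensus_cluster,
    generate_cohort,
    name_clusters,
    select_k,
    spearman_distance_matrix,
)
from icpipe.types import DegenerateInputError, ExpressionMatrix
from util_oracles import adjusted_rand_index, upgma_4point


def make_expr(matrix, genes=None, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{i}" for i in range(matrix.shape[1])]
    return ExpressionMatrix(pd.DataFrame(matrix, index=genes, columns=samples))


def three_cluster_expr(seed=7, n_per=20, shift=2.0, sd=0.5):
    """Three orthogonal marker blocks, one per cluster."""
    rng = np.random.default_rng(seed)
    n_genes = 120
    X = rng.normal(0, sd, (n_genes, 3 * n_per)) + rng.uniform(4, 10, n_genes)[:, None]
    labels = np.repeat([1, 2, 3], n_per)
    for c in range(3):
        X[c * 40:(c + 1) * 40][:, labels == c + 1] += shift
    return make_expr(X), labels


class TestSpearmanDistance:
    def test_duplicate_samples_distance_zero(self):
        expr = make_expr([[1, 1], [2, 2], [3, 3], [5, 5]])
        d = spearman_distance_matrix(expr)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_rank_reversal_distance_two(self):
        expr = make_expr([[1, 4], [2, 3], [3, 2], [4, 1]])
        d = spearman_distance_matrix(expr)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_pairwise_closed_form(self):
        from icpipe import spearman_rho

        expr = make_expr(
            [[1.0, 3.0, 2.0], [2.0, 1.0, 6.0], [3.0, 2.0, 4.0], [4.0, 5.0, 1.0]]
        )
        d = spearman_distance_matrix(expr)
        arr = expr.values.to_numpy()
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else 1 - spearman_rho(arr[:, i], arr[:, j])
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_named(self):
        expr = make_expr([[1, 5], [1, 6], [1, 7]], samples=["flat", "ok"])
        with pytest.raises(DegenerateInputError, match="flat"):
            spearman_distance_matrix(expr)

    def test_too_few_genes(self):
        with pytest.raises(DegenerateInputError, match="3 genes"):
            spearman_distance_matrix(make_expr([[1, 2], [2, 1]]))


class TestAverageLinkage:
    def test_two_identical_groups_split(self):
        d = np.zeros((4, 4))
        d[:2, 2:] = 5.0
        d[2:, :2] = 5.0
        labels = average_linkage_cluster(d, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_upgma_merge_heights_hand_computed(self):
        dist, heights = upgma_4point()
        z = hierarchy.linkage(squareform(dist), method="average")
        assert list(z[:, 2]) == pytest.approx(heights)
        labels = average_linkage_cluster(dist, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_n_singletons(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert sorted(average_linkage_cluster(d, 3)) == [1, 2, 3]

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            average_linkage_cluster(np.zeros((2, 2)), 3)


class TestConsensusCluster:
    def test_planted_two_clusters_recovered_exactly(self, config):
        cohort = generate_cohort(CohortSpec(seed=3))
        res = consensus_cluster(
            cohort.expression, cohort.truth.marker_genes, [2], config.replace(rng_seed=3)
        )
        truth = cohort.truth.cluster_labels.loc[res.labels[2].index]
        assert adjusted_rand_index(res.labels[2], truth) == pytest.approx(1.0)
        cm = res.consensus[2].to_numpy()
        same = truth.to_numpy()[:, None] == truth.to_numpy()[None, :]
        iu = np.triu_indices_from(cm, k=1)
        assert cm[iu][same[iu]].mean() >= 0.95
        assert cm[iu][~same[iu]].mean() <= 0.05

    def test_full_fraction_gives_binary_consensus(self, config):
        cohort = generate_cohort(CohortSpec(seed=1, n_samples=20, n_genes=300,
                                            n_driver_genes=20, n_null_genes=200))
        cfg = config.replace(consensus_subsample_fraction=1.0,
                             consensus_n_resamples=20, rng_seed=0)
        res = consensus_cluster(cohort.expression, None, [2], cfg)
        vals = np.unique(res.consensus[2].to_numpy())
        assert set(vals) <= {0.0, 1.0}

    def test_consensus_matrix_invariants(self, config):
        cohort = generate_cohort(CohortSpec(seed=2, n_samples=24, n_genes=300,
                                            n_driver_genes=20, n_null_genes=200))
        cfg = config.replace(consensus_n_resamples=60, rng_seed=5)
        res = consensus_cluster(cohort.expression, None, [2, 3], cfg)
        for k, cm in res.consensus.items():
            arr = cm.to_numpy()
            assert np.allclose(arr, arr.T)
            assert arr.min() >= 0 and arr.max() <= 1
            cs = res.cosample_counts.to_numpy()
            assert (np.diag(arr)[np.diag(cs) > 0] == 1.0).all()
            assert set(res.labels[k].unique()) == set(range(1, k + 1))

    def test_same_seed_bit_identical(self, config):
        cohort = generate_cohort(CohortSpec(seed=4, n_samples=24, n_genes=300,
                                            n_driver_genes=20, n_null_genes=200))
        cfg = config.replace(consensus_n_resamples=40, rng_seed=9)
        r1 = consensus_cluster(cohort.expression, None, [2, 3], cfg)
        r2 = consensus_cluster(cohort.expression, None, [2, 3], cfg)
        for k in (2, 3):
            pd.testing.assert_frame_equal(r1.consensus[k], r2.consensus[k])
            pd.testing.assert_series_equal(r1.labels[k], r2.labels[k])

    def test_labels_stable_across_seeds_on_separated_data(self, config):
        cohort = generate_cohort(CohortSpec(seed=5))
        labellings = []
        for seed in (1, 2, 3):
            res = consensus_cluster(cohort.expression, cohort.truth.marker_genes,
                                    [2], config.replace(rng_seed=seed,
                                                        consensus_n_resamples=100))
            labellings.append(res.labels[2])
        for other in labellings[1:]:
            assert adjusted_rand_index(labellings[0], other) == pytest.approx(1.0)


class TestSelectK:
    def test_two_cluster_data_selects_two(self, config):
        cohort = generate_cohort(CohortSpec(seed=6))
        res = consensus_cluster(cohort.expression, cohort.truth.marker_genes,
                                [2, 3, 4, 5], config.replace(rng_seed=6))
        assert res.k_selected == 2

    def test_three_cluster_data_selects_three(self, config):
        expr, labels = three_cluster_expr(seed=8)
        res = consensus_cluster(expr, None, [2, 3, 4, 5], config.replace(rng_seed=8))
        assert res.k_selected == 3
        assert adjusted_rand_index(res.labels[3], labels) == pytest.approx(1.0)

    def test_identical_stats_smallest_k(self):
        stats = pd.DataFrame({"k": [2, 3, 4], "cdf_area": [0.5, 0.5, 0.5],
                              "delta_area": [0.5, 0.0, 0.0]})
        assert select_k(stats) == 2

    def test_single_candidate_returned(self):
        stats = pd.DataFrame({"k": [3], "cdf_area": [0.4], "delta_area": [0.4]})
        assert select_k(stats) == 3


class TestNameClusters:
    def test_lexicographic_anchor(self):
        labels = pd.Series({"zeta": 1, "alpha": 2, "beta": 2})
        names = name_clusters(labels)
        assert names == {2: "IC1", 1: "IC2"}

    def test_reference_set_enrichment_anchor(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 2, "d": 2})
        es = pd.DataFrame(
            [[0.1, 0.2, 0.9, 0.8], [0.5, 0.5, 0.5, 0.5]],
            index=["OXPHOS", "OTHER"],
            columns=["a", "b", "c", "d"],
        )
        names = name_clusters(labels, es, ["OXPHOS"])
        assert names == {2: "IC1", 1: "IC2"}
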