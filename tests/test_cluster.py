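"""Consensus clustering: distance, embedding, alignment, stability scoring.

Independent oracles: textbook Pearson for the weighted distance, per-definition
silhouette recomputation, exhaustive-permutation label matching.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

from conftest import block_distance
from nbmeth.cluster import (
    CellResult,
    ClusterParams,
    ConsensusResult,
    align_labels,
    classify_samples,
    consensus_resample,
    kmeans_partition,
    select_solution,
    silhouette,
    tsne_embed,
    weighted_pearson_distance,
)
from nbmeth.simgen import SimConfig, generate_cohort


def _beta(p, n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0, 1, (p, n)),
        index=[f"cg{i}" for i in range(p)],
        columns=[f"S{i}" for i in range(n)],
    )


class TestWeightedPearsonDistance:
    def test_uniform_weights_match_textbook_pearson(self):
        beta = _beta(6, 3, seed=1)
        got = weighted_pearson_distance(beta).to_numpy()
        X = beta.to_numpy()
        n = X.shape[1]
        expected = np.zeros((n, n))
        for i in range(n):  # textbook formula oracle
            for j in range(n):
                xi, xj = X[:, i], X[:, j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / np.sqrt(
                    np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2)
                )
                expected[i, j] = 0.0 if i == j else 1.0 - r
        assert np.abs(got - expected).max() < 1e-12

    def test_identical_columns_distance_zero(self):
        beta = _beta(10, 1, seed=2)
        beta["S1"] = beta["S0"]
        assert weighted_pearson_distance(beta).loc["S0", "S1"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_negation_distance_two(self):
        beta = _beta(10, 1, seed=3)
        beta["S1"] = 1.0 - beta["S0"]  # β' = a − β stays in [0,1]
        assert weighted_pearson_distance(beta).loc["S0", "S1"] == pytest.approx(2.0, abs=1e-12)

    def test_weights_emphasise_probes(self):
        # two samples agree on probe block A, disagree on block B; weighting
        # block A drives distance to 0, weighting block B drives it up
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, 20)
        beta = pd.DataFrame({"S0": np.r_[a, a], "S1": np.r_[a, 1 - a]})
        wA = np.r_[np.ones(20), np.zeros(20) + 1e-12]
        wB = np.r_[np.zeros(20) + 1e-12, np.ones(20)]
        dA = weighted_pearson_distance(beta, wA).loc["S0", "S1"]
        dB = weighted_pearson_distance(beta, wB).loc["S0", "S1"]
        assert dA < 0.01 and dB > 1.9

    def test_zero_variance_sample_flagged(self):
        beta = _beta(5, 3)
        beta["S1"] = 0.5
        with pytest.raises(ValueError, match="S1"):
            weighted_pearson_distance(beta)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=12),
            elements=hst.floats(0, 1),
        )
    )
    def test_distance_matrix_properties(self, X):
        beta = pd.DataFrame(X)
        try:
            D = weighted_pearson_distance(
                beta, beta.std(axis=1, ddof=1).to_numpy() + 1e-6
            )
        except ValueError:
            return  # zero-weighted-variance sample: flagged error by contract
        d = D.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 2).all()


class TestTsneEmbed:
    def test_separated_groups_stay_separated(self):
        D, labels = block_distance([20, 20], within=0.02, between=1.8, seed=5)
        emb = tsne_embed(D, 2, ClusterParams(tsne_perplexity=10, tsne_max_iter=600), seed=1)
        from scipy.spatial.distance import pdist, squareform

        E = squareform(pdist(emb))
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert E[~same].min() > E[same & off_diag].max()

    def test_seed_determinism(self):
        D, _ = block_distance([10, 10], 0.05, 1.5, seed=6)
        p = ClusterParams(tsne_perplexity=5, tsne_max_iter=300)
        a = tsne_embed(D, 2, p, seed=9)
        b = tsne_embed(D, 2, p, seed=9)
        assert np.array_equal(a, b)

    def test_perplexity_bound_enforced(self):
        D, _ = block_distance([5, 5], 0.05, 1.5)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(D, 2, ClusterParams(tsne_perplexity=30))


class TestKmeansPartition:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(7)
        emb = np.r_[rng.normal(0, 0.1, (15, 2)), rng.normal(5, 0.1, (15, 2))]
        labels = kmeans_partition(emb, 2, restarts=5, seed=0)
        truth = np.r_[np.zeros(15), np.ones(15)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_distinct_points_zero_inertia(self):
        emb = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
        labels = kmeans_partition(emb, 4, restarts=5, seed=0)
        assert len(set(labels)) == 4

    def test_reproducible(self):
        rng = np.random.default_rng(8)
        emb = rng.normal(size=(30, 2))
        assert np.array_equal(
            kmeans_partition(emb, 3, seed=4), kmeans_partition(emb, 3, seed=4)
        )

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            kmeans_partition(np.zeros((3, 2)), 4)


class TestAlignLabels:
    def test_permutation_of_reference_restored(self):
        ref = np.array([0, 0, 1, 1, 2, 2])
        perm = np.array([2, 2, 0, 0, 1, 1])
        assert np.array_equal(align_labels(perm, ref), ref)

    def test_two_cluster_swap(self):
        assert np.array_equal(
            align_labels(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])),
            np.array([0, 0, 1, 1]),
        )

    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(9)
        ref = rng.integers(0, 5, 60)
        lab = rng.integers(0, 5, 60)
        aligned = align_labels(lab, ref)
        achieved = (aligned == ref).sum()
        best = max(
            sum(perm[v] == r for v, r in zip(lab, ref))
            for perm in map(
                lambda p: dict(zip(range(5), p)), itertools.permutations(range(5))
            )
        )
        assert achieved == best

    def test_partition_unchanged(self):
        rng = np.random.default_rng(10)
        ref = rng.integers(0, 4, 40)
        lab = rng.integers(0, 4, 40)
        assert adjusted_rand_score(lab, align_labels(lab, ref)) == 1.0

    def test_missing_samples_passed_through(self):
        ref = np.array([0, 0, 1, 1])
        lab = np.array([1, 1, -1, 0])
        out = align_labels(lab, ref)
        assert out[2] == -1


class TestSilhouette:
    def test_matches_per_definition_recomputation(self):
        D, labels = block_distance([2, 2, 2], within=0.3, between=1.0, seed=11)
        s, avg = silhouette(D, labels)
        d = D.to_numpy()
        expected = np.zeros(6)
        for i in range(6):  # per-definition oracle
            same = (labels == labels[i]) & (np.arange(6) != i)
            a = d[i, same].mean()
            b = min(d[i, labels == c].mean() for c in set(labels) - {labels[i]})
            expected[i] = (b - a) / max(a, b)
        assert np.abs(s - expected).max() < 1e-12
        assert avg == pytest.approx(expected.mean(), abs=1e-12)

    def test_perfect_separation(self):
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        s, avg = silhouette(d, np.array([0, 0, 1, 1]))
        assert np.allclose(s, 1.0) and avg == 1.0

    def test_equidistant_sample_scores_zero(self):
        # sample 0: a = d(0,1) = 0.5 and b = mean d to cluster 1 = 0.5
        d = np.array(
            [
                [0.0, 0.5, 0.5, 0.5],
                [0.5, 0.0, 0.9, 0.9],
                [0.5, 0.9, 0.0, 0.1],
                [0.5, 0.9, 0.1, 0.0],
            ]
        )
        s, _ = silhouette(d, np.array([0, 0, 1, 1]))
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            silhouette(d, np.array([0, 0, 0]))


def _fake_result(cells_spec):
    cells = {}
    n = 4
    for (dim, k), (repro, sil) in cells_spec.items():
        cells[(dim, k)] = CellResult(
            dim=dim, k=k, reference=np.zeros(n, int),
            modal_labels=np.zeros(n, int), modal_scores=np.full(n, repro),
            reproducibility=repro, sil_samples=np.full(n, sil), sil_avg=sil,
            n_success=10, n_iter=10, valid=True,
        )
    return ConsensusResult(cells=cells, sample_ids=pd.Index(range(n)), params=ClusterParams())


class TestSelectSolution:
    def test_dominating_cell_selected(self):
        res = _fake_result({(2, 3): (0.8, 0.3), (2, 5): (0.95, 0.6), (3, 5): (0.9, 0.5)})
        assert select_solution(res) == (2, 5)

    def test_rank_sum_tie_prefers_smaller_k(self):
        # (2,4) best repro/worst sil; (2,6) worst repro/best sil: tied rank sums
        res = _fake_result({(2, 4): (0.9, 0.2), (2, 6): (0.7, 0.8)})
        assert select_solution(res) == (2, 4)

    def test_tie_prefers_smaller_dim(self):
        res = _fake_result({(2, 5): (0.9, 0.5), (3, 5): (0.9, 0.5)})
        assert select_solution(res) == (2, 5)

    def test_invalid_cells_excluded(self):
        res = _fake_result({(2, 3): (0.8, 0.3), (2, 5): (0.99, 0.9)})
        res.cells[(2, 5)].valid = False
        assert select_solution(res) == (2, 3)


class TestClassifySamples:
    def _result(self, modal, sil):
        res = _fake_result({(2, 5): (0.9, 0.5)})
        c = res.cells[(2, 5)]
        c.modal_scores = np.array(modal)
        c.sil_samples = np.array(sil)
        res.selected = (2, 5)
        return res

    def test_boundaries_strict(self):
        res = self._result([0.70, 0.95, 1.0], [0.5, -0.01, 0.5])
        flags = classify_samples(res, 0.70)
        # modal exactly at threshold -> out; negative silhouette -> out
        assert list(flags) == [False, False, True]


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(
        n_samples=100, n_probes=4000, dmr_delta=0.4,
        ambiguous_fraction=0.0, cna_events=[], seed=21,
    )
    co = generate_cohort(cfg)
    from nbmeth.cluster import probe_weights

    dist = weighted_pearson_distance(co.beta, probe_weights(co.beta, "sd"))
    return co, dist


class TestConsensus:

    def test_planted_groups_recovered_with_high_stability(self, planted):
        co, dist = planted
        params = ClusterParams(
            dims_grid=(2,), k_grid=(5,), n_iter=32, tsne_max_iter=1000,
            tsne_perplexity=20, seed=1
        )
        res = consensus_resample(dist, params)
        cell = res.cells[(2, 5)]
        assert cell.valid
        assert (cell.modal_scores > 0.9).all()
        assert adjusted_rand_score(co.truth.true_cluster, cell.modal_labels) == 1.0

    def test_single_iteration_modal_scores_one(self, planted):
        _, dist = planted
        params = ClusterParams(
            dims_grid=(2,), k_grid=(3,), n_iter=1, tsne_max_iter=500,
            tsne_perplexity=20, seed=2
        )
        res = consensus_resample(dist, params)
        assert (res.cells[(2, 3)].modal_scores == 1.0).all()

    def test_subsample_perplexity_precondition(self):
        D, _ = block_distance([20, 20], 0.05, 1.5)
        with pytest.raises(ValueError, match="perplexity"):
            consensus_resample(D, ClusterParams(tsne_perplexity=15))

    def test_modal_scores_sample_order_invariant(self, planted):
        co, dist = planted
        params = ClusterParams(
            dims_grid=(2,), k_grid=(5,), n_iter=8, tsne_max_iter=500,
            tsne_perplexity=20, seed=3
        )
        res = consensus_resample(dist, params)
        assert res.cells[(2, 5)].reproducibility == pytest.approx(
            res.cells[(2, 5)].modal_scores.mean()
        )
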