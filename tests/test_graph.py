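import numpy as np
import pytest
from scipy import stats

from scnoise.counts import CountMatrix
from scnoise.graph import (
    PrunedKnnGraph,
    ClusterAssignment,
    cluster_graph,
    estimate_alpha_weight,
    fit_background,
    knn_search,
    link_probability,
    prune_links,
    select_pcs,
    transition_probabilities,
    _two_sided_nb_p,
)
from scnoise.normalization import fit_offset_model, pearson_residuals
from scnoise.simulate import simulate_homogeneous
from tests.conftest import make_cm


class TestSelectPcs:
    def test_rank3(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(200, 3))
        B = rng.normal(size=(3, 500))
        X = A @ B + 1e-6 * rng.normal(size=(200, 500))
        assert select_pcs(X, max_pcs=100).n_components == 3

    def test_isotropic_small_d(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 500))
        assert select_pcs(X, max_pcs=100).n_components < 10

    def test_cap(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(200, 20))
        B = rng.normal(size=(20, 500))
        X = A @ B + 1e-6 * rng.normal(size=(200, 500))
        assert select_pcs(X, max_pcs=5).n_components == 5

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        emb = select_pcs(rng.normal(size=(50, 80)), max_pcs=20)
        assert np.all(np.diff(emb.explained_variance) <= 1e-12)

    def test_fewer_cells_than_components(self):
        rng = np.random.default_rng(4)
        emb = select_pcs(rng.normal(size=(50, 8)), max_pcs=100)
        assert emb.n_components <= 7


class TestKnnSearch:
    def test_collinear(self):
        coords = np.array([[0.0], [1.0], [3.0]])
        nbr, dist = knn_search(coords, k=1)
        assert nbr[:, 0].tolist() == [1, 0, 1]

    def test_duplicates_self_excluded(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        nbr, dist = knn_search(coords, k=2)
        assert nbr[0, 0] == 1 and dist[0, 0] == 0.0
        assert nbr[1, 0] == 0 and dist[1, 0] == 0.0
        assert 0 not in nbr[0][0:0]  # self never returned
        assert all(nbr[j, 0] != j for j in range(3))

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(200, 7))
        nbr, dist = knn_search(coords, k=25)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for j in range(200):
            order = np.lexsort((np.arange(200), d2[j]))[:25]
            assert nbr[j].tolist() == order.tolist()

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="k="):
            knn_search(np.zeros((5, 2)), k=5)


class TestBackground:
    def test_equal_weights_mean(self, rng):
        counts = rng.poisson(4.0, size=(30, 10)).astype(np.int64)
        cm = make_cm(counts)
        bg = fit_background(cm, np.arange(10), alpha_weight=1.0)
        np.testing.assert_allclose(bg.mu_local, counts.mean(axis=1), rtol=1e-12)

    def test_dispersion_recovery(self):
        # sigma^2 = mu + mu^2/2 across a wide mean range -> r ~ 2 at high mean
        rng = np.random.default_rng(0)
        mu = 10.0 ** rng.uniform(-0.5, 1.8, size=800)
        r = 2.0
        X = rng.negative_binomial(r, r / (r + mu[:, None]), size=(800, 200)).astype(np.int64)
        bg = fit_background(make_cm(X), np.arange(200))
        high = bg.mu_local > 10
        assert np.median(bg.r_background[high]) == pytest.approx(2.0, rel=0.25)

    def test_underdispersed_gets_upper_clip(self):
        # constant-ish counts: fitted variance <= mean -> near-Poisson clip
        rng = np.random.default_rng(1)
        X = rng.poisson(50.0, size=(100, 50)).astype(np.int64)
        bg = fit_background(make_cm(X), np.arange(50))
        assert (bg.r_background[bg.mu_local > 0] >= 1e2).any()
        assert bg.r_background[bg.mu_local > 0].max() <= 1e6

    def test_all_zero_gene_sentinel(self):
        counts = np.array([[0, 0, 0], [5, 6, 7]])
        bg = fit_background(make_cm(counts), np.arange(3))
        assert bg.mu_local[0] == 0.0
        assert np.isinf(bg.r_background[0])


class TestAlphaWeight:
    def test_identical_neighbors(self, rng):
        col = rng.poisson(5.0, size=40).astype(np.int64)
        counts = np.tile(col[:, None], (1, 6))
        cm = make_cm(counts)
        assert estimate_alpha_weight(cm, np.arange(1, 6), central=0) == 1.0

    def test_wildly_different_central_caps(self, rng):
        n_genes = 40
        counts = np.zeros((n_genes, 6), dtype=np.int64)
        counts[: n_genes // 2, 0] = 1000  # central expresses half the genes
        counts[n_genes // 2 :, 1:] = 1000  # neighbors express the other half
        cm = make_cm(counts)
        alpha = estimate_alpha_weight(cm, np.arange(1, 6), central=0, satisfied_fraction=0.99)
        assert alpha == 1024.0

    def test_matches_bruteforce_scan(self, rng):
        from scnoise.graph import alpha_constraint_satisfied

        counts = rng.poisson(3.0, size=(60, 12)).astype(np.int64)
        counts[:, 0] += rng.poisson(2.0, size=60)
        cm = make_cm(counts)
        neighbors = np.arange(1, 12)
        got = estimate_alpha_weight(cm, neighbors, central=0)
        # brute-force scan over the grid is the oracle by definition
        expected = 1024.0
        for alpha in [2.0**i for i in range(11)]:
            if alpha_constraint_satisfied(cm, neighbors, 0, alpha):
                expected = alpha
                break
        assert got == expected


class TestPruneLinks:
    def test_null_links_kept(self, rng):
        counts = rng.poisson(5.0, size=(100, 40)).astype(np.int64)
        cm = make_cm(counts)
        nbr, dist = knn_search(rng.normal(size=(40, 3)), k=5)
        g = prune_links(cm, nbr, dist, prune_threshold=1e-3)
        assert g.kept.mean() > 0.95

    def test_extreme_gene_pruned(self):
        # one gene with local mean 2 (post-pseudocount 3), neighbor count 200, r=2
        # oracle: evaluate the NB upper tail numerically
        oracle = 2.0 * stats.nbinom.sf(200, 2, 2 / (2 + 3.0))
        assert oracle * 1000 < 1e-3
        got = _two_sided_nb_p(np.array([201.0]), np.array([3.0]), np.array([2.0]))
        assert got[0] == pytest.approx(oracle, rel=1e-9)
        assert got[0] * 1000 < 1e-3

    def test_median_two_sided_capped(self):
        mu, r = 10.0, 5.0
        med = stats.nbinom.median(r, r / (r + mu))
        p = _two_sided_nb_p(np.array([float(med)]), np.array([mu]), np.array([r]))
        assert p[0] == 1.0

    def test_anti_monotone_in_threshold(self, rng):
        counts = rng.poisson(3.0, size=(80, 30)).astype(np.int64)
        counts[:40, :5] *= 8
        cm = make_cm(counts)
        nbr, dist = knn_search(rng.normal(size=(30, 3)), k=6)
        g_lo = prune_links(cm, nbr, dist, prune_threshold=1e-4)
        g_hi = prune_links(cm, nbr, dist, prune_threshold=1e-2)
        assert not (g_hi.kept & ~g_lo.kept).any()

    def test_homogeneous_low_prune_rate(self):
        s = simulate_homogeneous(n_genes=300, n_cells=150, seed=9)
        cm = s.counts
        res = pearson_residuals(cm, fit_offset_model(cm, mode="analytic"))
        nbr, dist = knn_search(select_pcs(res, max_pcs=50), k=15)
        g = prune_links(cm, nbr, dist, prune_threshold=1e-3)
        assert (~g.kept).mean() <= 0.05


class TestLinkProbability:
    def test_worked_example(self):
        p = link_probability(np.array([1e-4, 1e-3, 1e-2, 0.5, 1.0]))
        assert p == pytest.approx(1e-3, rel=1e-6)

    def test_all_zero_floor(self):
        assert link_probability(np.zeros(5)) == pytest.approx(1e-16, rel=1e-9)

    def test_all_one(self):
        assert link_probability(np.ones(4)) == pytest.approx(1.0, abs=1e-15)

    def test_fewer_than_three(self):
        assert link_probability(np.array([1e-4])) == pytest.approx(1e-4, rel=1e-9)


def _make_planted_graph(rng, n=100, p_intra=1.0, prob_inter=1e-6):
    """Two 50-cell cliques joined by a single weak link."""
    k = 10
    neighbors = np.zeros((n, k), dtype=np.int64)
    probs = np.full((n, k), p_intra)
    for j in range(n):
        block = range(0, 50) if j < 50 else range(50, 100)
        others = [m for m in block if m != j]
        neighbors[j] = rng.choice(others, k, replace=False)
    neighbors[0, 0] = 50  # the single bridge
    probs[0, 0] = prob_inter
    return PrunedKnnGraph(
        k=k, neighbors=neighbors, distances=np.zeros((n, k)),
        link_pvalues=probs.copy(), link_probabilities=probs,
        kept=np.ones((n, k), dtype=bool), prune_threshold=0.0,
    )


class TestClustering:
    def test_two_cliques(self, rng):
        g = _make_planted_graph(rng)
        cl = cluster_graph(g, method="leiden", resolution=1.0, seed=1)
        assert cl.labels.max() == 2
        assert len(set(cl.labels[:50])) == 1
        assert len(set(cl.labels[50:])) == 1

    def test_single_clique_one_cluster(self, rng):
        k = 5
        neighbors = np.array([[m for m in range(6) if m != j][:k] for j in range(6)])
        g = PrunedKnnGraph(
            k=k, neighbors=neighbors, distances=np.zeros((6, k)),
            link_pvalues=np.ones((6, k)), link_probabilities=np.ones((6, k)),
            kept=np.ones((6, k), dtype=bool), prune_threshold=0.0,
        )
        cl = cluster_graph(g, seed=0)
        assert cl.labels.max() == 1

    def test_resolution_monotone(self, rng):
        g = _make_planted_graph(rng)
        counts = [
            cluster_graph(g, resolution=r, seed=3).labels.max()
            for r in (0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts)

    def test_disconnected_singletons(self):
        g = PrunedKnnGraph(
            k=1, neighbors=np.array([[1], [0], [3], [2]]), distances=np.zeros((4, 1)),
            link_pvalues=np.ones((4, 1)), link_probabilities=np.ones((4, 1)),
            kept=np.zeros((4, 1), dtype=bool), prune_threshold=1e-3,
        )
        cl = cluster_graph(g, seed=0)
        assert cl.labels.tolist() == [1, 2, 3, 4]

    def test_deterministic(self, rng):
        g = _make_planted_graph(rng)
        a = cluster_graph(g, seed=7).labels
        b = cluster_graph(g, seed=7).labels
        np.testing.assert_array_equal(a, b)


class TestTransitions:
    def _graph_with_probs(self, probs_between):
        # 4 cells: {0,1} cluster 1, {2,3} cluster 2; links 0-2 etc.
        n_links = len(probs_between)
        k = n_links
        neighbors = np.zeros((4, k), dtype=np.int64)
        probs = np.ones((4, k))
        kept = np.zeros((4, k), dtype=bool)
        for t, p in enumerate(probs_between):
            neighbors[0, t] = 2
            probs[0, t] = p
            kept[0, t] = True
        g = PrunedKnnGraph(
            k=k, neighbors=neighbors, distances=np.zeros((4, k)),
            link_pvalues=probs.copy(), link_probabilities=probs,
            kept=kept, prune_threshold=0.0,
        )
        labels = ClusterAssignment(labels=np.array([1, 1, 2, 2]), method="leiden", resolution=1.0)
        return g, labels

    def test_uniform_links(self):
        g, cl = self._graph_with_probs([0.1, 0.1, 0.1])
        tm = transition_probabilities(g, cl)
        assert tm.values[0, 1] == pytest.approx(0.1, rel=1e-9)

    def test_geometric_mean(self):
        g, cl = self._graph_with_probs([1e-2, 1e-4])
        tm = transition_probabilities(g, cl)
        assert tm.values[0, 1] == pytest.approx(1e-3, rel=1e-9)

    def test_no_connecting_links_zero(self):
        g, cl = self._graph_with_probs([0.5])
        g.kept[:] = False
        tm = transition_probabilities(g, cl)
        assert tm.values[0, 1] == 0.0
        assert tm.values[0, 0] == 1.0

    def test_symmetric(self):
        g, cl = self._graph_with_probs([0.2, 0.4])
        tm = transition_probabilities(g, cl)
        np.testing.assert_allclose(tm.values, tm.values.T)
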