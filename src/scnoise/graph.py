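"""Pruned k-nearest-neighbor graph over the cell-state manifold.

Pipeline: PCA of the Pearson residuals with an elbow criterion, k-d-tree
neighbor search, local negative-binomial background models per central
cell, two-sided outlier tests on every candidate link with Bonferroni
correction, link probabilities from the top-3 corrected p-values, and a
pruning mask.  Community detection and cluster transition probabilities
operate on the kept links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from scnoise.counts import CountMatrix

logger = logging.getLogger(__name__)

LINK_PSEUDO = 1e-16
_R_CLIP = (1e-3, 1e6)


@dataclass
class Embedding:
    coordinates: np.ndarray  # cells x d
    n_components: int
    explained_variance: np.ndarray  # per-component fraction, full spectrum


@dataclass
class BackgroundModel:
    """Local NB background for one central cell.

    ``r_background`` is derived from a quadratic fit of log variance against
    log mean across the genes of the neighborhood:
    r = mu^2 / (var_fit - mu), clipped to [1e-3, 1e6]; genes whose fitted
    variance does not exceed the mean get the upper clip (near-Poisson).
    """

    mu_local: np.ndarray  # per-gene weighted mean of raw counts
    meanvar_coefficients: tuple[float, float, float]
    r_background: np.ndarray
    alpha_weight: float = 1.0

    def predicted_sd(self) -> np.ndarray:
        var = self.mu_local + self.mu_local**2 / self.r_background
        return np.sqrt(np.maximum(var, 0.0))


@dataclass
class PrunedKnnGraph:
    k: int
    neighbors: np.ndarray  # cells x k neighbor indices, ascending distance
    distances: np.ndarray  # cells x k
    link_pvalues: np.ndarray  # cells x k, Bonferroni-corrected min gene p
    link_probabilities: np.ndarray  # cells x k
    kept: np.ndarray  # cells x k bool
    prune_threshold: float

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]

    def kept_neighbors(self, j: int) -> np.ndarray:
        return self.neighbors[j][self.kept[j]]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-cell, contiguous from 1
    method: str
    resolution: float


@dataclass
class TransitionMatrix:
    values: np.ndarray  # clusters x clusters, symmetric, diag 1


# ---------------------------------------------------------------------------
# PCA / knn


def _elbow(frac: np.ndarray, limit: int) -> int:
    """Smallest d whose explained-variance decrement sits in the noise floor.

    delta_d = frac[d] - frac[d+1] is compared against one standard deviation
    around the mean of all later decrements (with a small absolute tolerance
    so an exactly flat floor fires).  A premature fire on near-degenerate
    structure components is vetoed unless the gain frac[d] itself is close
    to the mean gain of everything beyond d.
    """
    if len(frac) < 4:
        return min(len(frac), limit)
    diffs = frac[:-1] - frac[1:]
    tol = 1e-3 * frac.mean()
    for d in range(1, limit):
        later = diffs[d + 1 :] if d + 1 < len(diffs) else diffs[len(diffs) :]
        if later.size < 2:
            break
        in_floor = diffs[d] <= later.mean() + later.std(ddof=0) + tol
        # veto only clear cliffs: the Marchenko-Pastur edge of a pure noise
        # floor sits below 4x the bulk mean, real structure far above 8x
        no_cliff = frac[d] <= 8.0 * frac[d:].mean()
        if in_floor and no_cliff:
            return d
    return limit


def select_pcs(residuals, max_pcs: int = 100) -> Embedding:
    """PCA of residuals with elbow-based component selection.

    Genes are centered, not scaled.  The embedding is truncated at the
    smallest d where the explained-variance gain of adding one more
    component is within one standard deviation of the gains of all later
    components (up to ``max_pcs``).
    """
    mat = residuals.residuals if hasattr(residuals, "residuals") else np.asarray(residuals)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 cells for PCA")
    X = mat.T  # cells x genes
    X = X - X.mean(axis=0, keepdims=True)
    limit = min(max_pcs, X.shape[0] - 1, X.shape[1])
    # full spectrum up to `limit` via SVD
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    ev = (S**2) / max(X.shape[0] - 1, 1)
    frac = ev / ev.sum() if ev.sum() > 0 else ev
    d = _elbow(frac, limit)
    coords = U[:, :d] * S[:d]
    return Embedding(coordinates=coords, n_components=d, explained_variance=frac)


def knn_search(embedding, k: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """k nearest other cells per cell by Euclidean distance.

    Returns ``(neighbors, distances)``, each cells x k, sorted by ascending
    distance with ties broken by lower cell index.  Uses a k-d tree; the
    self point is never returned.
    """
    coords = embedding.coordinates if hasattr(embedding, "coordinates") else np.asarray(embedding)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    tree = cKDTree(coords)
    # query extra neighbors so distance ties at the k-boundary can be
    # re-ordered deterministically by index
    m = min(n, k + 8)
    dist, idx = tree.query(coords, k=m)
    neighbors = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k))
    for j in range(n):
        mask = idx[j] != j
        d_j, i_j = dist[j][mask], idx[j][mask]
        order = np.lexsort((i_j, d_j))
        neighbors[j] = i_j[order][:k]
        distances[j] = d_j[order][:k]
    return neighbors, distances


# ---------------------------------------------------------------------------
# Background models


def _fit_meanvar(mu: np.ndarray, var: np.ndarray) -> tuple[float, float, float]:
    """Quadratic fit of log variance vs log mean over expressed genes.

    The fit is made robust by iteratively trimming genes far above the
    curve: outlier cells inside the neighborhood inflate the variance of
    the genes they distort, and an unprotected least-squares fit would
    absorb them into the background and mask the outlier test.
    """
    ok = (mu > 0) & (var > 0)
    lm, lv = np.log(mu[ok]), np.log(var[ok])
    if ok.sum() < 3 or np.ptp(lm) == 0:
        return (float(lv.mean()) if ok.any() else 0.0, 0.0, 0.0)
    deg = 2 if len(np.unique(lm)) > 2 else 1
    keep = np.ones(len(lm), dtype=bool)
    coef = np.polyfit(lm, lv, deg)
    for _ in range(3):
        resid = lv - np.polyval(coef, lm)
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        if mad == 0:
            break
        new_keep = resid <= np.median(resid[keep]) + 4.0 * mad
        if new_keep.sum() < max(3, deg + 1) or np.array_equal(new_keep, keep):
            keep = new_keep if new_keep.sum() >= max(3, deg + 1) else keep
            break
        keep = new_keep
        coef = np.polyfit(lm[keep], lv[keep], deg)
    if deg == 1:
        coef = np.concatenate([[0.0], coef])
    c2, c1, c0 = coef
    return (float(c0), float(c1), float(c2))


def _background_r(mu: np.ndarray, coefficients: tuple[float, float, float]) -> np.ndarray:
    c0, c1, c2 = coefficients
    r = np.full_like(mu, np.inf, dtype=float)
    pos = mu > 0
    lm = np.log(mu[pos])
    var_fit = np.exp(c0 + c1 * lm + c2 * lm**2)
    excess = var_fit - mu[pos]
    r_pos = np.where(excess > 0, mu[pos] ** 2 / np.where(excess > 0, excess, 1.0), _R_CLIP[1])
    r[pos] = np.clip(r_pos, *_R_CLIP)
    return r


def fit_background(
    cm: CountMatrix,
    neighborhood: np.ndarray,
    alpha_weight: float = 1.0,
    link_weights: np.ndarray | None = None,
) -> BackgroundModel:
    """Local NB background model for a neighborhood.

    ``neighborhood`` lists the central cell first, followed by its
    neighbors.  The per-gene local mean is a weighted mean with the central
    cell weighted ``alpha_weight * max(link_weights)``.
    """
    neighborhood = np.asarray(neighborhood)
    if len(neighborhood) < 2:
        raise ValueError("need at least 2 cells in the neighborhood")
    sub = cm.counts[:, neighborhood].astype(float)
    if link_weights is None:
        link_weights = np.ones(len(neighborhood) - 1)
    w = np.concatenate([[alpha_weight * (link_weights.max() if len(link_weights) else 1.0)], link_weights])
    w = w / w.sum()
    mu = sub @ w
    # local per-gene variance (unweighted) feeds the mean-variance fit
    var = sub.var(axis=1, ddof=1)
    coefficients = _fit_meanvar(mu, var)
    r = _background_r(mu, coefficients)
    return BackgroundModel(mu_local=mu, meanvar_coefficients=coefficients, r_background=r,
                           alpha_weight=alpha_weight)


ALPHA_GRID = tuple(float(2**i) for i in range(11))  # 1 .. 1024


def alpha_constraint_satisfied(
    cm: CountMatrix,
    neighbors: np.ndarray,
    central: int,
    alpha: float,
    satisfied_fraction: float = 0.95,
) -> bool:
    """Whether the alpha-weighted local mean is compatible with the central cell.

    A gene is compatible when the weighted local mean lies within one
    background-model standard deviation of the central cell's count.  The
    mean weights the central cell by ``alpha``; the mean-variance fit that
    yields the standard deviation uses the neighbors only, so the central
    cell cannot vouch for itself.
    """
    neighbors = np.asarray(neighbors)
    x_c = cm.counts[:, central].astype(float)
    nb = cm.counts[:, neighbors].astype(float)
    k = len(neighbors)
    m = (alpha * x_c + nb.sum(axis=1)) / (alpha + k)
    var_nb = nb.var(axis=1, ddof=1) if k > 1 else np.zeros_like(x_c)
    coefficients = _fit_meanvar(m, var_nb)
    r = _background_r(m, coefficients)
    sd = np.sqrt(np.maximum(m + m**2 / r, 0.0))
    expressed = (m > 0) | (x_c > 0)
    if not expressed.any():
        return True
    ok = np.abs(x_c[expressed] - m[expressed]) <= sd[expressed]
    return bool(ok.mean() >= satisfied_fraction)


def estimate_alpha_weight(
    cm: CountMatrix,
    neighbors: np.ndarray,
    central: int,
    satisfied_fraction: float = 0.95,
) -> float:
    """Self-consistent central-cell weight.

    Returns the smallest alpha on the grid {1, 2, 4, ..., 1024} such that
    the alpha-weighted local mean lies within one background-model standard
    deviation of the central cell's count for at least
    ``satisfied_fraction`` of expressed genes; the cap if never satisfied.
    """
    neighbors = np.asarray(neighbors)
    if len(neighbors) == 0:
        raise ValueError("empty neighborhood")
    for alpha in ALPHA_GRID:
        if alpha_constraint_satisfied(cm, neighbors, central, alpha, satisfied_fraction):
            return alpha
    return ALPHA_GRID[-1]


# ---------------------------------------------------------------------------
# Link tests


def _two_sided_nb_p(x: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Two-sided NB tail p: min(1, 2 * min(P(X<=x), P(X>=x))).

    Parameterization: mean mu, size r (variance mu + mu^2/r).  Infinite r
    falls back to Poisson.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    p_lo = np.empty_like(mu)
    p_hi = np.empty_like(mu)
    fin = np.isfinite(r)
    if fin.any():
        size = r[fin]
        prob = size / (size + mu[fin])
        p_lo[fin] = stats.nbinom.cdf(x[fin], size, prob)
        p_hi[fin] = stats.nbinom.sf(x[fin] - 1, size, prob)
    if (~fin).any():
        p_lo[~fin] = stats.poisson.cdf(x[~fin], mu[~fin])
        p_hi[~fin] = stats.poisson.sf(x[~fin] - 1, mu[~fin])
    return np.minimum(1.0, 2.0 * np.minimum(p_lo, p_hi))


def link_probability(corrected_pvalues: np.ndarray) -> float:
    """Geometric mean of the top-3 smallest corrected p-values (+1e-16)."""
    p = np.sort(np.asarray(corrected_pvalues, dtype=float))
    if p.size == 0:
        return 1.0
    top = p[: min(3, p.size)] + LINK_PSEUDO
    return float(np.exp(np.mean(np.log(top))))


def prune_links(
    cm: CountMatrix,
    neighbors: np.ndarray,
    distances: np.ndarray | None = None,
    backgrounds: list[BackgroundModel] | None = None,
    prune_threshold: float = 1e-3,
    alpha_weight: float = 1.0,
    reweight: bool = True,
) -> PrunedKnnGraph:
    """Test every candidate link against the central cell's background model.

    For each link and gene, the neighbor's count (pseudocount 1 added to
    counts and local means) is tested two-sided against
    NB(mu_local + 1, r_background); per-gene p-values are Bonferroni
    corrected by the number of tested genes and capped at 1.  The link
    p-value is the minimum corrected gene p; the link probability is the
    top-3 geometric mean.  Links with probability below ``prune_threshold``
    are pruned.

    With ``reweight`` (default), a second pass recomputes each background
    with neighbor weights set to the first-pass link probabilities, so
    neighbors already flagged as incompatible stop contaminating the local
    mean and variance they are tested against.
    """
    n, k = neighbors.shape
    G = cm.n_genes
    counts = cm.counts

    def _pass(weights: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        pvals = np.ones((n, k))
        probs = np.ones((n, k))
        for j in range(n):
            if backgrounds is not None and weights is None:
                bg = backgrounds[j]
            else:
                w = None if weights is None else np.maximum(weights[j], LINK_PSEUDO)
                bg = fit_background(
                    cm, np.concatenate([[j], neighbors[j]]),
                    alpha_weight=alpha_weight, link_weights=w,
                )
            mu1 = bg.mu_local + 1.0  # pseudocount on local means
            r = bg.r_background
            x1 = counts[:, neighbors[j]].astype(float) + 1.0  # genes x k, pseudocount
            p = _two_sided_nb_p(
                x1,
                np.broadcast_to(mu1[:, None], x1.shape),
                np.broadcast_to(r[:, None], x1.shape),
            )
            p_corr = np.minimum(1.0, p * G)
            pvals[j] = p_corr.min(axis=0)
            psort = np.sort(p_corr, axis=0)
            top = psort[: min(3, G), :] + LINK_PSEUDO
            probs[j] = np.exp(np.mean(np.log(top), axis=0))
        return pvals, np.clip(probs, LINK_PSEUDO, 1.0)

    link_pvalues, link_probs = _pass(None)
    if reweight:
        link_pvalues, link_probs = _pass(link_probs)
    kept = link_probs >= prune_threshold
    if distances is None:
        distances = np.zeros((n, k))
    n_pruned = int((~kept).sum())
    logger.info("prune_links: pruned %d/%d links at threshold %g", n_pruned, n * k, prune_threshold)
    return PrunedKnnGraph(
        k=k,
        neighbors=neighbors,
        distances=distances,
        link_pvalues=link_pvalues,
        link_probabilities=link_probs,
        kept=kept,
        prune_threshold=prune_threshold,
    )


# ---------------------------------------------------------------------------
# Clustering / transitions


def _build_igraph(graph: PrunedKnnGraph):
    import igraph as ig

    edges = {}
    for j in range(graph.n_cells):
        for t in range(graph.k):
            if graph.kept[j, t]:
                a, b = j, int(graph.neighbors[j, t])
                key = (min(a, b), max(a, b))
                w = float(graph.link_probabilities[j, t])
                edges[key] = max(edges.get(key, 0.0), w)
    g = ig.Graph(n=graph.n_cells, edges=list(edges.keys()))
    g.es["weight"] = [max(w, LINK_PSEUDO) for w in edges.values()]
    return g


def cluster_graph(
    graph: PrunedKnnGraph,
    method: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Community detection on the kept-link graph, weighted by link probability."""
    g = _build_igraph(graph)
    if g.ecount() == 0:
        logger.warning("fully disconnected graph: every cell becomes its own cluster")
        labels = np.arange(1, graph.n_cells + 1)
        return ClusterAssignment(labels=labels, method=method, resolution=resolution)
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        membership = np.asarray(part.membership)
    elif method == "louvain":
        rng = np.random.default_rng(seed)
        ig_seed = int(rng.integers(2**31 - 1))
        import igraph as ig  # noqa: F401

        import random

        state = random.getstate()
        random.seed(ig_seed)
        try:
            part = g.community_multilevel(weights="weight", resolution=resolution)
        finally:
            random.setstate(state)
        membership = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # relabel contiguous from 1, ordered by first occurrence
    _, labels = np.unique(membership, return_inverse=True)
    return ClusterAssignment(labels=labels + 1, method=method, resolution=resolution)


def transition_probabilities(graph: PrunedKnnGraph, clusters: ClusterAssignment) -> TransitionMatrix:
    """Cluster-to-cluster connectivity: geometric mean of connecting link probabilities."""
    labels = clusters.labels
    ids = np.unique(labels)
    nc = len(ids)
    pos = {c: i for i, c in enumerate(ids)}
    logs: dict[tuple[int, int], list[float]] = {}
    for j in range(graph.n_cells):
        for t in range(graph.k):
            if not graph.kept[j, t]:
                continue
            a, b = labels[j], labels[int(graph.neighbors[j, t])]
            if a == b:
                continue
            key = (pos[min(a, b)], pos[max(a, b)])
            logs.setdefault(key, []).append(np.log(graph.link_probabilities[j, t]))
    values = np.zeros((nc, nc))
    np.fill_diagonal(values, 1.0)
    for (a, b), ls in logs.items():
        v = float(np.exp(np.mean(ls)))
        values[a, b] = values[b, a] = v
    return TransitionMatrix(values=values)
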