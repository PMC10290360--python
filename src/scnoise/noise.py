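"""Residual-noise estimation in homogeneous neighborhoods.

For each central cell j with kept neighbors, per-cell size factors
beta = n / mean(n) are fitted with a one-parameter Gamma(a, a) to give the
technical dispersion r_t.  Per gene, counts in the neighborhood are modeled
as NB(mu, r = r_t / eps') where eps' >= 1 inflates the technical
dispersion; the residual noise is eps = (eps' - 1) / r_t >= 0.  eps is
inferred by MAP with a Cauchy(0, gamma) prior truncated to eps >= 0.

The per-neighborhood fits are vectorized across genes: the NB
log-likelihood depends on the counts only through sufficient statistics
(sum of counts, number of zeros, and gammaln at the nonzero values), so a
shared log-spaced grid over eps' brackets the optimum for every gene at
once, followed by a vectorized golden-section refinement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from scnoise.counts import CountMatrix
from scnoise.graph import PrunedKnnGraph

logger = logging.getLogger(__name__)

_ALPHA_BOUNDS = (1e-2, 1e4)
_EPSP_MAX = 1e6
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class NeighborhoodModel:
    """Fitted per-neighborhood quantities for one central cell."""

    central: int
    members: np.ndarray
    mu: np.ndarray  # per-gene arithmetic mean over members
    beta: np.ndarray  # per-member size factors, mean exactly 1
    r_technical: float


@dataclass
class NoiseMatrix:
    """Per-gene, per-central-cell residual noise estimates.

    Entries are NaN where the local mean is zero or below the expression
    threshold, or where the neighborhood was too small to fit.
    """

    epsilon: np.ndarray  # genes x cells
    epsilon_prime: np.ndarray  # genes x cells, >= 1 where defined
    cellular_noise: np.ndarray  # per-cell mean of defined epsilon
    r_technical: np.ndarray  # per-cell
    gamma_prior: float
    prior_location: float = 0.0
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None


def compute_beta(cm: CountMatrix, members: np.ndarray) -> np.ndarray:
    """Size factors beta_m = n_m / mean(n) over the neighborhood; mean(beta) = 1."""
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("members must be non-empty")
    n = cm.total_counts[members].astype(float)
    mean_n = n.mean()
    if mean_n == 0:
        raise ValueError("all total counts are zero in the neighborhood")
    return n / mean_n


def _gamma_loglik(log_a: float, beta: np.ndarray, log_beta_sum: float, beta_sum: float) -> float:
    a = np.exp(log_a)
    m = len(beta)
    return m * (a * log_a - gammaln(a)) + (a - 1.0) * log_beta_sum - a * beta_sum


def fit_gamma_dispersion(beta: np.ndarray) -> float:
    """ML fit of Gamma(shape=a, rate=a) to the size factors; returns a = r_t.

    Optimized over log a in [log 1e-2, log 1e4].  Numerically constant beta
    returns the upper bound with a degenerate-fit warning.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size < 3:
        raise ValueError("need at least 3 members to fit the Gamma dispersion")
    if np.any(beta <= 0):
        raise ValueError("all size factors must be positive")
    if np.ptp(beta) < 1e-12:
        warnings.warn("degenerate (constant) size factors; returning upper dispersion bound")
        return _ALPHA_BOUNDS[1]
    lbs = float(np.log(beta).sum())
    bs = float(beta.sum())
    lo, hi = np.log(_ALPHA_BOUNDS[0]), np.log(_ALPHA_BOUNDS[1])
    res = minimize_scalar(
        lambda t: -_gamma_loglik(t, beta, lbs, bs),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# Vectorized NB log-likelihood profile over eps'


class _NeighborhoodLikelihood:
    """Sufficient-statistic NB log-likelihood for all genes of one neighborhood.

    Constant terms that do not depend on the dispersion (gammaln(x+1)) are
    dropped; argmax over eps' is unaffected.
    """

    def __init__(self, counts_sub: np.ndarray, mu: np.ndarray) -> None:
        # counts_sub: genes x members
        self.n_members = counts_sub.shape[1]
        self.mu = np.asarray(mu, dtype=float)
        gi, ci = np.nonzero(counts_sub)
        self.nz_gene = gi
        self.nz_val = counts_sub[gi, ci].astype(float)
        self.n_zero = self.n_members - np.bincount(gi, minlength=counts_sub.shape[0])
        self.x_sum = counts_sub.sum(axis=1).astype(float)

    def loglik_shared_r(self, r: float) -> np.ndarray:
        """Log-likelihood per gene at a single dispersion r shared by all genes."""
        G = len(self.mu)
        out = np.zeros(G)
        np.add.at(out, self.nz_gene, gammaln(self.nz_val + r))
        out += self.n_zero * gammaln(r)
        out -= self.n_members * gammaln(r)
        with np.errstate(divide="ignore", invalid="ignore"):
            out += self.n_members * r * np.log(r / (r + self.mu))
            out += self.x_sum * np.where(self.mu > 0, np.log(self.mu / (r + self.mu)), 0.0)
        return out

    def loglik_per_gene_r(self, r: np.ndarray) -> np.ndarray:
        """Log-likelihood per gene at gene-specific dispersions r (vectorized)."""
        G = len(self.mu)
        out = np.zeros(G)
        np.add.at(out, self.nz_gene, gammaln(self.nz_val + r[self.nz_gene]))
        out += (self.n_zero - self.n_members) * gammaln(r)
        with np.errstate(divide="ignore", invalid="ignore"):
            out += self.n_members * r * np.log(r / (r + self.mu))
            out += self.x_sum * np.where(self.mu > 0, np.log(self.mu / (r + self.mu)), 0.0)
        return out


def _log_prior(eps: np.ndarray, gamma: float) -> np.ndarray:
    """Log density of a Cauchy(0, gamma) truncated to eps >= 0 (constants dropped)."""
    return -np.log1p((eps / gamma) ** 2)


def _posterior_at(t: np.ndarray, lik: _NeighborhoodLikelihood, r_t: float, gamma: float | None) -> np.ndarray:
    """Objective at per-gene log(eps') values t."""
    epsp = np.exp(t)
    r = r_t / epsp
    val = lik.loglik_per_gene_r(r)
    if gamma is not None:
        eps = (epsp - 1.0) / r_t
        val = val + _log_prior(eps, gamma)
    return val


def _fit_epsilon_batch(
    counts_sub: np.ndarray,
    mu: np.ndarray,
    r_technical: float,
    gamma_prior: float | None,
    n_grid: int = 64,
    n_refine: int = 36,
) -> tuple[np.ndarray, np.ndarray]:
    """MAP (or ML if gamma_prior is None) of eps for all genes of a neighborhood.

    A shared log-spaced grid over eps' in [1, 1e6] brackets the optimum per
    gene; a vectorized golden-section pass refines within the bracketing
    interval.  Returns (epsilon, epsilon_prime) with NaN where mu == 0.
    """
    G = len(mu)
    lik = _NeighborhoodLikelihood(counts_sub, mu)
    grid_t = np.linspace(0.0, np.log(_EPSP_MAX), n_grid)
    obj = np.empty((n_grid, G))
    for g, t in enumerate(grid_t):
        r = r_technical / np.exp(t)
        val = lik.loglik_shared_r(r)
        if gamma_prior is not None:
            eps = (np.exp(t) - 1.0) / r_technical
            val = val + _log_prior(np.full(G, eps), gamma_prior)
        obj[g] = val
    best = np.argmax(obj, axis=0)
    lo = grid_t[np.maximum(best - 1, 0)]
    hi = grid_t[np.minimum(best + 1, n_grid - 1)]

    # vectorized golden-section maximization on t = log(eps')
    a, b = lo.copy(), hi.copy()
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = _posterior_at(c, lik, r_technical, gamma_prior)
    fd = _posterior_at(d, lik, r_technical, gamma_prior)
    for _ in range(n_refine):
        take_left = fc >= fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = _posterior_at(c, lik, r_technical, gamma_prior)
        fd = _posterior_at(d, lik, r_technical, gamma_prior)
        if np.max(b - a) < 1e-10:
            break
    t_hat = (a + b) / 2.0
    epsp = np.exp(t_hat)
    eps = (epsp - 1.0) / r_technical
    undefined = mu <= 0
    eps = np.where(undefined, np.nan, eps)
    epsp = np.where(undefined, np.nan, epsp)
    return eps, epsp


def map_epsilon(
    counts: np.ndarray,
    mu: float,
    r_technical: float,
    gamma_prior: float = 1.0,
    mode: str = "map",
) -> tuple[float, float]:
    """Residual-noise estimate for a single gene.

    Maximizes sum_l log NB(x_l | mu, r = r_t/eps') plus, in ``map`` mode,
    the log Cauchy(0, gamma) prior on eps = (eps' - 1)/r_t, over
    log(eps') in [0, log 1e6].  Returns ``(epsilon, epsilon_prime)``; a
    non-positive mean yields ``(nan, nan)``.
    """
    if mode not in ("map", "ml"):
        raise ValueError(f"unknown mode {mode!r}")
    if r_technical <= 0:
        raise ValueError("r_technical must be positive")
    if mode == "map" and gamma_prior <= 0:
        raise ValueError("gamma_prior must be positive in map mode")
    if mu <= 0:
        return (float("nan"), float("nan"))
    counts_sub = np.asarray(counts, dtype=np.int64).reshape(1, -1)
    gamma = gamma_prior if mode == "map" else None
    eps, epsp = _fit_epsilon_batch(counts_sub, np.array([mu]), r_technical, gamma)
    return float(eps[0]), float(epsp[0])


def joint_map(
    counts: np.ndarray,
    r_technical: float,
    gamma_prior: float = 1.0,
) -> tuple[float, float, bool]:
    """Diagnostic joint MAP over (mu, eps).

    Alternates a 1-D grid over mu around the arithmetic mean with the
    eps-profile fit.  Returns ``(mu_hat, epsilon_hat, collapsed)`` where
    ``collapsed`` flags runs in which mu_hat fell toward 0 despite a
    positive arithmetic mean (a known spurious local optimum).
    """
    counts = np.asarray(counts, dtype=np.int64)
    xbar = counts.mean()
    if xbar == 0:
        return (0.0, float("nan"), False)
    # profile over a mu grid spanning well below and above the mean
    mu_grid = np.concatenate([np.linspace(1e-3, xbar * 3, 80), [xbar]])
    best_val, best_mu, best_eps = -np.inf, xbar, np.nan
    lik_counts = counts.reshape(1, -1)
    for mu in mu_grid:
        lik = _NeighborhoodLikelihood(lik_counts, np.array([mu]))
        eps, epsp = _fit_epsilon_batch(lik_counts, np.array([mu]), r_technical, gamma_prior)
        t = np.log(epsp)
        val = float(_posterior_at(t, lik, r_technical, gamma_prior)[0])
        # include the count-constant term so values are comparable across mu
        if val > best_val:
            best_val, best_mu, best_eps = val, float(mu), float(eps[0])
    collapsed = bool(best_mu < 0.1 * xbar)
    return (best_mu, best_eps, collapsed)


def fit_neighborhood(cm: CountMatrix, central: int, members: np.ndarray) -> NeighborhoodModel:
    """Size factors, local means and technical dispersion for one neighborhood."""
    members = np.asarray(members)
    beta = compute_beta(cm, members)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_t = fit_gamma_dispersion(beta)
    mu = cm.counts[:, members].mean(axis=1)
    return NeighborhoodModel(central=central, members=members, mu=mu, beta=beta, r_technical=r_t)


def noise_matrix(
    cm: CountMatrix,
    graph: PrunedKnnGraph,
    gamma_prior: float = 1.0,
    min_expression: float = 0.0,
    mode: str = "map",
) -> NoiseMatrix:
    """Residual noise for every gene and central cell of a pruned graph.

    Members of each neighborhood are the central cell plus its kept
    neighbors.  Neighborhoods pruned below 3 members yield an all-missing
    column.  Genes with local mean below ``min_expression`` are missing.
    Cellular noise is the mean over defined entries per cell.
    """
    if gamma_prior <= 0 and mode == "map":
        raise ValueError("gamma_prior must be positive")
    n_cells, G = cm.n_cells, cm.n_genes
    eps = np.full((G, n_cells), np.nan)
    epsp = np.full((G, n_cells), np.nan)
    r_tech = np.full(n_cells, np.nan)
    gamma = gamma_prior if mode == "map" else None
    n_small = 0
    for j in range(n_cells):
        members = np.concatenate([[j], graph.kept_neighbors(j)])
        if len(members) < 3:
            n_small += 1
            continue
        nb = fit_neighborhood(cm, j, members)
        r_tech[j] = nb.r_technical
        sub = cm.counts[:, members]
        e, ep = _fit_epsilon_batch(sub, nb.mu, nb.r_technical, gamma)
        low = nb.mu < min_expression
        e[low] = np.nan
        ep[low] = np.nan
        eps[:, j] = e
        epsp[:, j] = ep
    if n_small:
        logger.warning("%d neighborhoods had fewer than 3 members after pruning; columns left missing", n_small)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cellular = np.nanmean(eps, axis=0)
    return NoiseMatrix(
        epsilon=eps,
        epsilon_prime=epsp,
        cellular_noise=cellular,
        r_technical=r_tech,
        gamma_prior=gamma_prior if mode == "map" else np.inf,
        gene_ids=cm.gene_ids,
        cell_ids=cm.cell_ids,
    )


def calibrate_gamma(
    cm: CountMatrix,
    graph: PrunedKnnGraph,
    gamma_grid: np.ndarray | list[float],
    min_expression: float = 0.0,
) -> tuple[float, dict[float, float]]:
    """Choose the prior scale minimizing |corr(cellular noise, total counts)|.

    Returns ``(gamma, profile)`` where ``profile`` maps each candidate to
    its absolute Pearson correlation.
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma_grid must be non-empty")
    profile: dict[float, float] = {}
    for gamma in gamma_grid:
        nm = noise_matrix(cm, graph, gamma_prior=gamma, min_expression=min_expression)
        ok = np.isfinite(nm.cellular_noise)
        if ok.sum() < 3 or np.std(nm.cellular_noise[ok]) == 0:
            profile[gamma] = 1.0
            continue
        c = np.corrcoef(nm.cellular_noise[ok], cm.total_counts[ok])[0, 1]
        profile[gamma] = float(abs(c))
    best = min(gamma_grid, key=lambda g: profile[g])
    logger.info("calibrate_gamma: chose gamma=%g (|corr| profile: %s)", best, profile)
    return best, profile
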