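"""Differential-noise testing between cell groups and cross-dataset mapping."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from scnoise.noise import NoiseMatrix

logger = logging.getLogger(__name__)

_FC_PSEUDO = 1e-3


@dataclass
class DiffNoiseTable:
    """Per-gene differential-noise results between two groups."""

    table: pd.DataFrame  # columns: gene, mean_noise_a, mean_noise_b, log2_fold_change, p_value, p_adjusted
    excluded_genes: list[str]


@dataclass
class MedoidMapping:
    """Nonnegative simplex weights expressing B medoids in terms of A medoids."""

    weights: np.ndarray  # clusters_B x clusters_A, rows sum to 1
    residual_norms: np.ndarray  # per B medoid


def diff_noisy_genes(
    noise: NoiseMatrix,
    labels: np.ndarray,
    group_a,
    group_b,
    k_neighbors: int = 25,
    seed: int = 0,
) -> DiffNoiseTable:
    """Two-sided Wilcoxon rank-sum test of noise levels between two groups.

    A uniform[0, 1] pseudocount (independent per gene and cell, seeded) is
    added to each noise value first.  The p-value is Bonferroni corrected
    across genes, conservatively scaled up by ``k_neighbors``, and capped
    at 1.  The fold change is log2((mean_a + 1e-3)/(mean_b + 1e-3)) on the
    raw (un-pseudocounted) means.
    """
    labels = np.asarray(labels.labels if hasattr(labels, "labels") else labels)
    in_a = labels == group_a
    in_b = labels == group_b
    if not in_a.any() or not in_b.any():
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    eps = noise.epsilon
    G = eps.shape[0]
    gene_ids = noise.gene_ids if noise.gene_ids is not None else np.arange(G).astype(str)

    rows = []
    excluded: list[str] = []
    # pre-draw pseudocounts per gene x cell for reproducibility
    pseudo = rng.uniform(0.0, 1.0, size=eps.shape)
    tested = []
    for i in range(G):
        a_all, b_all = eps[i, in_a], eps[i, in_b]
        ok_a, ok_b = np.isfinite(a_all), np.isfinite(b_all)
        if not ok_a.any() or not ok_b.any():
            excluded.append(str(gene_ids[i]))
            continue
        tested.append((i, a_all[ok_a], b_all[ok_b], pseudo[i, in_a][ok_a], pseudo[i, in_b][ok_b]))
    n_tested = len(tested)
    for i, a, b, pa, pb in tested:
        av = a + pa
        bv = b + pb
        method = "exact" if (av.size <= 20 and bv.size <= 20) else "asymptotic"
        res = stats.mannwhitneyu(av, bv, alternative="two-sided", method=method)
        p = float(res.pvalue)
        p_adj = min(1.0, p * n_tested * k_neighbors)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        l2fc = float(np.log2((mean_a + _FC_PSEUDO) / (mean_b + _FC_PSEUDO)))
        rows.append(
            dict(
                gene=str(gene_ids[i]),
                mean_noise_a=mean_a,
                mean_noise_b=mean_b,
                log2_fold_change=l2fc,
                p_value=p,
                p_adjusted=p_adj,
            )
        )
    if excluded:
        logger.info("diff_noisy_genes: %d genes excluded for all-missing noise", len(excluded))
    return DiffNoiseTable(table=pd.DataFrame(rows), excluded_genes=excluded)


def _simplex_lsq(A: np.ndarray, b: np.ndarray, penalty: float = 1e6) -> tuple[np.ndarray, float]:
    """min ||b - A^T w||^2 s.t. w >= 0, sum(w) = 1.

    Solved as penalized NNLS (Lawson-Hanson with an appended equality row),
    then renormalized so the simplex constraint holds exactly.
    """
    n_a = A.shape[0]
    scale = max(np.abs(b).max(), np.abs(A).max(), 1.0)
    rho = penalty * scale
    M = np.vstack([A.T, np.full((1, n_a), rho)])
    y = np.concatenate([b, [rho]])
    w, _ = nnls(M, y)
    s = w.sum()
    if s <= 0:
        w = np.full(n_a, 1.0 / n_a)
    else:
        w = w / s
    resid = float(np.linalg.norm(b - A.T @ w))
    return w, resid


def qp_map_clusters(medoids_a: np.ndarray, medoids_b: np.ndarray) -> MedoidMapping:
    """Express each B medoid as a convex combination of A medoids.

    Solves, for each row b of ``medoids_b``, the quadratic program
    min ||b - W^T medoids_a||^2 with W >= 0 and sum(W) = 1.
    """
    medoids_a = np.asarray(medoids_a, dtype=float)
    medoids_b = np.asarray(medoids_b, dtype=float)
    if medoids_a.shape[1] != medoids_b.shape[1]:
        raise ValueError("medoid matrices must share the gene axis")
    gram = medoids_a @ medoids_a.T
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        logger.warning("rank-deficient Gram matrix; solution may not be unique")
    nb = medoids_b.shape[0]
    weights = np.empty((nb, medoids_a.shape[0]))
    resid = np.empty(nb)
    for r in range(nb):
        weights[r], resid[r] = _simplex_lsq(medoids_a, medoids_b[r])
    return MedoidMapping(weights=weights, residual_norms=resid)
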