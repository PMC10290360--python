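"""Depth normalization of UMI counts and Pearson residual computation.

Two modes are provided.  ``regression`` performs a per-gene Poisson GLM of
counts on log total UMI counts (optionally with batch indicator covariates),
smooths the coefficients across genes of similar mean expression with LOESS,
and then infers a per-gene negative-binomial dispersion by maximum
likelihood with the mean model held fixed.  ``analytic`` is the closed-form
shortcut: slope fixed to 1, offset equal to the log total count, and the
intercept chosen so that predicted gene totals match observed gene totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from scnoise.counts import CountMatrix

logger = logging.getLogger(__name__)

_THETA_BOUNDS = (1e-4, 1e6)


@dataclass
class OffsetModel:
    """Per-gene mean model mu_ij = exp(intercept_i + slope * log n_j + batch)."""

    intercepts: np.ndarray
    slope: float
    dispersions: np.ndarray
    mode: str
    batch_coefficients: np.ndarray | None = None  # genes x (n_batches - 1)
    batch_levels: np.ndarray | None = None
    gene_ids: np.ndarray | None = None

    def predict_mean(self, cm: CountMatrix, batch_labels: Sequence | None = None) -> np.ndarray:
        """Predicted means mu_ij (genes x cells) for the cells of ``cm``."""
        log_n = np.log(cm.total_counts.astype(float))
        eta = self.intercepts[:, None] + self.slope * log_n[None, :]
        if self.batch_coefficients is not None:
            if batch_labels is None:
                raise ValueError("model was fitted with batches; batch_labels required")
            dummies = _batch_dummies(np.asarray(batch_labels), self.batch_levels)
            eta = eta + self.batch_coefficients @ dummies.T
        return np.exp(eta)


@dataclass
class ResidualMatrix:
    """Clipped Pearson residuals, genes x cells."""

    residuals: np.ndarray
    clip_bound: float
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None


def _batch_dummies(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Dummy encoding against the first level; cells x (len(levels)-1)."""
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.zeros((len(labels), 0))


def _nb_loglik_theta(log_theta: float, x: np.ndarray, mu: np.ndarray) -> float:
    theta = np.exp(log_theta)
    return float(
        np.sum(
            gammaln(x + theta)
            - gammaln(theta)
            - gammaln(x + 1)
            + theta * np.log(theta / (theta + mu))
            + x * np.log(mu / (theta + mu), where=mu > 0, out=np.zeros_like(mu))
        )
    )


def _ml_dispersion(x: np.ndarray, mu: np.ndarray) -> float:
    """Brent ML of the NB size parameter theta with the mean model fixed."""
    lo, hi = np.log(_THETA_BOUNDS[0]), np.log(_THETA_BOUNDS[1])
    res = minimize_scalar(
        lambda t: -_nb_loglik_theta(t, x, mu), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _loess_smooth(values: np.ndarray, order_by: np.ndarray, span: float) -> np.ndarray:
    """LOESS of ``values`` against ``order_by`` evaluated at the data points."""
    if len(values) < 5:
        return values
    sm_vals = lowess(values, order_by, frac=span, return_sorted=False)
    return np.where(np.isfinite(sm_vals), sm_vals, values)


def fit_offset_model(
    cm: CountMatrix,
    mode: str = "analytic",
    batch_labels: Sequence | None = None,
    theta: float | None = None,
    loess_span: float = 0.75,
    smooth_dispersion: bool = True,
) -> OffsetModel:
    """Fit the per-gene depth-offset model.

    Parameters
    ----------
    cm
        Filtered count matrix.
    mode
        ``"regression"`` (Poisson GLM + LOESS + ML dispersion) or
        ``"analytic"`` (slope 1, offset log n_j, matched gene totals).
    batch_labels
        Optional per-cell batch labels; dummy-encoded against the first
        level and included as covariates (regression mode only).
    theta
        If given, fixes the dispersion for all genes instead of ML.
    """
    if cm.n_cells < 2:
        raise ValueError("need at least 2 cells to fit the offset model")
    if mode not in ("regression", "analytic"):
        raise ValueError(f"unknown mode {mode!r}")
    if batch_labels is not None and len(batch_labels) != cm.n_cells:
        raise ValueError("batch_labels must cover all cells")

    x = cm.counts.astype(float)
    n = cm.total_counts.astype(float)
    log_n = np.log(n)
    gene_totals = x.sum(axis=1)
    grand_total = n.sum()

    if mode == "analytic":
        with np.errstate(divide="ignore"):
            intercepts = np.log(gene_totals / grand_total)
        slope = 1.0
        batch_coef = None
        levels = None
        mu = np.exp(intercepts[:, None] + log_n[None, :])
    else:
        levels = None
        dummies = np.zeros((cm.n_cells, 0))
        if batch_labels is not None:
            labels = np.asarray(batch_labels)
            levels = np.unique(labels)
            dummies = _batch_dummies(labels, levels)
        design = sm.add_constant(np.column_stack([log_n, dummies]))
        n_coef = design.shape[1]
        coefs = np.full((cm.n_genes, n_coef), np.nan)
        fit_mask = gene_totals > 0
        for i in np.where(fit_mask)[0]:
            try:
                res = sm.GLM(x[i], design, family=sm.families.Poisson()).fit()
                coefs[i] = res.params
            except Exception:  # noqa: BLE001 - rare separation failures
                fit_mask[i] = False
        if not fit_mask.any():
            raise ValueError("no gene could be fitted in regression mode")
        log_mean = np.log(np.maximum(gene_totals / cm.n_cells, 1e-12))
        for c in range(n_coef):
            coefs[fit_mask, c] = _loess_smooth(
                coefs[fit_mask, c], log_mean[fit_mask], loess_span
            )
        # zero-total genes: analytic fallback keeps downstream shapes intact
        coefs[~fit_mask, 0] = -np.inf
        coefs[~fit_mask, 1:] = 0.0
        # the smoothed slope is gene-shared downstream only in analytic mode;
        # regression mode keeps per-gene slopes folded into the intercept via
        # a single representative slope (median) plus per-gene offset so the
        # OffsetModel surface stays 1-slope.  Predicted means are computed
        # here from the full per-gene coefficients.
        eta = coefs[:, 0][:, None] + coefs[:, 1][:, None] * log_n[None, :]
        if dummies.shape[1]:
            eta = eta + coefs[:, 2:] @ dummies.T
        mu = np.exp(eta)
        slope = float(np.median(coefs[fit_mask, 1]))
        # re-derive intercepts consistent with the shared slope at the mean depth
        intercepts = coefs[:, 0] + (coefs[:, 1] - slope) * log_n.mean()
        batch_coef = coefs[:, 2:] if dummies.shape[1] else None

    if theta is not None:
        dispersions = np.full(cm.n_genes, float(theta))
    else:
        dispersions = np.full(cm.n_genes, _THETA_BOUNDS[1])
        for i in range(cm.n_genes):
            if gene_totals[i] > 0:
                dispersions[i] = _ml_dispersion(x[i], np.maximum(mu[i], 1e-12))
        if smooth_dispersion:
            ok = gene_totals > 0
            log_mean = np.log(np.maximum(gene_totals / cm.n_cells, 1e-12))
            dispersions[ok] = np.exp(
                _loess_smooth(np.log(dispersions[ok]), log_mean[ok], loess_span)
            )
        dispersions = np.clip(dispersions, *_THETA_BOUNDS)

    model = OffsetModel(
        intercepts=intercepts,
        slope=slope if mode == "analytic" else slope,
        dispersions=dispersions,
        mode=mode,
        batch_coefficients=batch_coef,
        batch_levels=levels,
        gene_ids=cm.gene_ids,
    )
    if mode == "analytic":
        model.slope = 1.0
    # stash full regression means for exact residuals in regression mode
    model._mu_cache = mu  # type: ignore[attr-defined]
    model._cell_ids_cache = cm.cell_ids  # type: ignore[attr-defined]
    return model


def pearson_residuals(
    cm: CountMatrix,
    model: OffsetModel,
    clip: float | None = None,
    batch_labels: Sequence | None = None,
) -> ResidualMatrix:
    """Pearson residuals (x - mu) / sqrt(mu + mu^2/theta), clipped.

    The clip bound defaults to sqrt(n_cells).  Entries with mu = 0 for a
    retained gene are defined as 0.
    """
    if model.gene_ids is not None and not np.array_equal(model.gene_ids, cm.gene_ids):
        raise ValueError("model was fitted on a different gene set")
    cached = getattr(model, "_mu_cache", None)
    cached_cells = getattr(model, "_cell_ids_cache", None)
    if cached is not None and cached_cells is not None and np.array_equal(cached_cells, cm.cell_ids):
        mu = cached
    else:
        mu = model.predict_mean(cm, batch_labels=batch_labels)
    theta = model.dispersions[:, None]
    var = mu + mu**2 / theta
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (cm.counts - mu) / np.sqrt(var)
    res[~np.isfinite(res)] = 0.0
    n_zero_mu = int((mu == 0).any(axis=1).sum())
    if n_zero_mu:
        logger.warning("%d genes had zero predicted mean for some cell; residuals set to 0", n_zero_mu)
    bound = float(clip) if clip is not None else float(np.sqrt(cm.n_cells))
    res = np.clip(res, -bound, bound)
    return ResidualMatrix(res, clip_bound=bound, gene_ids=cm.gene_ids, cell_ids=cm.cell_ids)
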