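"""Noise estimation from smFISH spot counts.

Spot counts per cell are modeled as NB with variance mu + eps_f * mu^2;
eps_f (the reciprocal of the NB size parameter) is the residual-noise
analog for imaging data, where no shared depth-variability term is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln


@dataclass
class FishNoiseEstimate:
    mu: float
    epsilon_f: float
    se: float
    n: int
    method: str
    boundary: bool = False  # variance <= mean in ml mode


@dataclass
class SpotCountTable:
    """Per-cell nuclear and cytoplasmic spot counts."""

    table: pd.DataFrame  # columns: cell_id, compartment_nuclear, compartment_cytoplasmic

    @classmethod
    def read(cls, path) -> "SpotCountTable":
        df = pd.read_csv(path, sep="\t")
        required = {"cell_id", "compartment_nuclear", "compartment_cytoplasmic"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"spot-count table missing columns: {sorted(missing)}")
        if (df[["compartment_nuclear", "compartment_cytoplasmic"]] < 0).any().any():
            raise ValueError("negative spot counts")
        return cls(df)

    @property
    def nuclear(self) -> np.ndarray:
        return self.table["compartment_nuclear"].to_numpy(dtype=np.int64)

    @property
    def whole_cell(self) -> np.ndarray:
        return self.nuclear + self.table["compartment_cytoplasmic"].to_numpy(dtype=np.int64)


def _eps_point(x: np.ndarray, method: str) -> tuple[float, bool]:
    xbar = x.mean()
    if method == "moments":
        s2 = x.var(ddof=1)
        return max(0.0, (s2 - xbar) / xbar**2), False
    # ml: mu fixed at the sample mean (its NB MLE); 1-D over log eps_f
    s2 = x.var(ddof=1)
    if s2 <= xbar:
        return 0.0, True

    def negll(log_eps: float) -> float:
        r = 1.0 / np.exp(log_eps)
        return -float(
            np.sum(
                gammaln(x + r) - gammaln(r) - gammaln(x + 1)
                + r * np.log(r / (r + xbar))
                + x * np.log(xbar / (r + xbar))
            )
        )

    res = minimize_scalar(negll, bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
                          options={"xatol": 1e-8})
    return float(np.exp(res.x)), False


def fit_fish_noise(
    counts: np.ndarray,
    method: str = "ml",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> FishNoiseEstimate:
    """Fit eps_f from per-cell spot counts.

    ``moments``: eps_f = max(0, (s^2 - xbar) / xbar^2).
    ``ml``: NB maximum likelihood with the mean fixed at the sample mean.
    The standard error comes from a seeded nonparametric bootstrap.
    """
    x = np.asarray(counts, dtype=np.int64)
    if x.size < 10:
        raise ValueError("need at least 10 cells")
    if x.mean() <= 0:
        raise ValueError("mean spot count must be positive")
    if method not in ("ml", "moments"):
        raise ValueError(f"unknown method {method!r}")
    eps, boundary = _eps_point(x.astype(float), method)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        xb = rng.choice(x, size=x.size, replace=True).astype(float)
        if xb.mean() <= 0:
            boots[b] = np.nan
            continue
        boots[b], _ = _eps_point(xb, method)
    se = float(np.nanstd(boots, ddof=1))
    return FishNoiseEstimate(
        mu=float(x.mean()), epsilon_f=float(eps), se=se, n=int(x.size),
        method=method, boundary=boundary,
    )


def noise_ratio(nuclear: FishNoiseEstimate, cellular: FishNoiseEstimate) -> tuple[float, float]:
    """Nuclear / whole-cell noise ratio with a delta-method standard error.

    Compartments are treated as independent:
    se(ratio)^2 = (se_n / eps_c)^2 + (eps_n * se_c / eps_c^2)^2.
    """
    if cellular.epsilon_f <= 0:
        raise ValueError("cellular noise estimate is zero; ratio undefined")
    ratio = nuclear.epsilon_f / cellular.epsilon_f
    se = float(
        np.sqrt(
            (nuclear.se / cellular.epsilon_f) ** 2
            + (nuclear.epsilon_f * cellular.se / cellular.epsilon_f**2) ** 2
        )
    )
    return float(ratio), se
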