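"""Spike-in-calibrated highly variable gene detection.

Technical noise is summarized by regressing the squared coefficient of
variation of the spike-ins on their mean normalized expression,
CV^2 = a1/mu + a0 (the Brennecke-style mean-CV^2 trend).  A gene whose
CV^2 exceeds the trend is scored with

    T_g = (n_cells - 1) * CV^2_g / trend(mu_g)  ~  chi^2_{n_cells - 1}

under the technical-noise null, upper tail, with Benjamini-Hochberg control
across genes.  Genes flagged at the chosen FDR form the clustering gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError
from .normalize import NormalizedMatrix

__all__ = ["TrendFit", "fit_spikein_trend", "gene_mean_cv2", "call_hvgs"]

MIN_SPIKEINS = 5


@dataclass
class TrendFit:
    a1: float  # 1/mu coefficient
    a0: float  # asymptotic CV^2, >= 0
    n_spikeins_used: int

    def predict(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a1 / mu + self.a0


def gene_mean_cv2(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and squared coefficient of variation of normalized values."""
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    return mu, cv2


def fit_spikein_trend(nm: NormalizedMatrix) -> TrendFit:
    """Fit CV^2 = a1/mu + a0 across spike-ins by iteratively reweighted
    least squares (weights 1/fitted^2, appropriate for the multiplicative
    sampling noise of a CV^2 estimate)."""
    spikes = nm.values[nm.is_spikein]
    mu, cv2 = gene_mean_cv2(spikes)
    usable = (mu > 0) & np.isfinite(cv2)
    if usable.sum() < MIN_SPIKEINS:
        raise EstimationError(
            f"need >= {MIN_SPIKEINS} spike-ins with positive mean, "
            f"got {int(usable.sum())}"
        )
    x, y = 1.0 / mu[usable], cv2[usable]
    if np.ptp(x) < 1e-12 * max(1.0, float(np.abs(x).max())):
        raise EstimationError(
            "all spike-in means equal: the mean-CV^2 design is rank-deficient"
        )
    X = np.column_stack([x, np.ones_like(x)])
    w = np.ones_like(y)
    coef = np.zeros(2)
    for _ in range(30):
        sw = np.sqrt(w)
        new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.allclose(new, coef, rtol=1e-10, atol=1e-12):
            coef = new
            break
        coef = new
        fitted = np.clip(X @ coef, 1e-8, None)
        w = 1.0 / fitted**2
    a1, a0 = float(coef[0]), float(coef[1])
    if a1 < 0:
        warnings.warn("negative fitted 1/mu coefficient; clamping a1 to 0", stacklevel=2)
        a1 = 0.0
    a0 = max(a0, 0.0)
    if a1 == 0.0 and a0 == 0.0:
        raise EstimationError("degenerate spike-in trend (a1 = a0 = 0)")
    return TrendFit(a1=a1, a0=a0, n_spikeins_used=int(usable.sum()))


def call_hvgs(
    nm: NormalizedMatrix,
    fit: TrendFit,
    fdr: float = 0.1,
    include_spikeins: bool = False,
) -> pd.DataFrame:
    """Flag genes whose CV^2 significantly exceeds the spike-in trend.

    Returns a gene-indexed table with columns ``mean``, ``cv2``,
    ``fitted_cv2``, ``p``, ``q`` and ``is_hvg``.  Genes with zero mean get
    p = 1.  Only genes passing the low-expression filter are eligible to be
    flagged (their statistics are still reported).
    """
    if not 0 < fdr <= 1:
        raise ValueError(f"fdr must be in (0, 1], got {fdr}")
    keep = np.ones(nm.n_genes, dtype=bool) if include_spikeins else ~nm.is_spikein
    mu, cv2 = gene_mean_cv2(nm.values)
    fitted = fit.predict(mu)
    n = nm.n_cells
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (n - 1) * cv2 / fitted
    p = np.ones(nm.n_genes)
    ok = (mu > 0) & np.isfinite(T) & keep
    p[ok] = stats.chi2.sf(T[ok], df=n - 1)
    q = np.ones(nm.n_genes)
    eligible = ok & nm.filter_mask
    if eligible.any():
        q[eligible] = multipletests(p[eligible], method="fdr_bh")[1]
    is_hvg = eligible & (q <= fdr)
    return pd.DataFrame(
        {
            "mean": mu,
            "cv2": cv2,
            "fitted_cv2": fitted,
            "p": p,
            "q": q,
            "is_hvg": is_hvg,
        },
        index=pd.Index(nm.gene_ids, name="gene_id"),
    )
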