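"""Posterior selection and estimation from a sampled chain.

Selection works on the marginal posterior probabilities of inclusion
(PPIs): ppi_pj is the fraction of retained draws in which xi_pj = 1.
Two thresholding rules are provided — the median probability model
(PPI > 0.5) and thresholding of the estimated Bayesian false discovery
rate

    FDR(c) = sum_pj (1 - ppi_pj) D_pj / sum_pj D_pj,   D_pj = 1(ppi_pj > c),

where the optimal c' for a target rate alpha is the smallest threshold
on the grid of observed PPI values with FDR(c') < alpha (the estimator
is piecewise constant on that grid, so the search is exact).  All
thresholds are strict: a PPI exactly equal to the threshold is not
selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sampler import PosteriorChain

__all__ = [
    "SelectionResult",
    "compute_ppi",
    "median_model",
    "bayesian_fdr",
    "fdr_threshold",
    "beta_summaries",
    "select",
]


def compute_ppi(chain: PosteriorChain, burn_in: int | None = None) -> np.ndarray:
    """Marginal posterior inclusion probabilities, P x J in [0, 1]."""
    keep = chain.retained(burn_in)
    return chain.xi_draws[keep].mean(axis=0)


def median_model(ppi: np.ndarray) -> np.ndarray:
    """Median probability model: indicators with PPI strictly above 0.5."""
    return (np.asarray(ppi) > 0.5).astype(np.uint8)


def bayesian_fdr(ppi: np.ndarray, c: float) -> float:
    """Estimated Bayesian FDR of the selection {ppi > c}.

    Returns 0.0 when the selection is empty.
    """
    if not 0.0 <= c < 1.0:
        raise ValueError("threshold c must lie in [0, 1)")
    ppi = np.asarray(ppi, dtype=np.float64)
    D = ppi > c
    n_sel = int(D.sum())
    if n_sel == 0:
        return 0.0
    return float(np.sum((1.0 - ppi)[D]) / n_sel)


def fdr_threshold(ppi: np.ndarray, alpha_level: float) -> tuple[float, bool]:
    """Smallest PPI-grid threshold c' with FDR(c') < alpha_level.

    Searching the grid {0} plus the sorted unique PPI values maximizes
    the number of selections subject to the bound, because FDR(c) is
    piecewise constant between observed PPIs.  Returns ``(c', attained)``;
    when no threshold satisfies the bound, c' is the maximum PPI (empty
    selection) and ``attained`` is False.
    """
    if not 0.0 < alpha_level < 1.0:
        raise ValueError("alpha_level must lie in (0, 1)")
    ppi = np.asarray(ppi, dtype=np.float64)
    grid = np.concatenate([[0.0], np.unique(ppi)])
    for c in grid:
        if c >= 1.0:
            continue
        if bayesian_fdr(ppi, float(c)) < alpha_level and np.any(ppi > c):
            return float(c), True
    return float(ppi.max()), False


def beta_summaries(
    chain: PosteriorChain,
    burn_in: int | None = None,
    conditional: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and median of each beta_pj.

    With ``conditional=True`` the summaries are over the draws in which
    the coefficient was included (0 where never included); otherwise over
    all retained draws, zeros included.
    """
    keep = chain.retained(burn_in)
    beta = chain.beta_draws[keep]
    if not conditional:
        return beta.mean(axis=0), np.median(beta, axis=0)
    xi = chain.xi_draws[keep].astype(bool)
    n_inc = xi.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_inc > 0, beta.sum(axis=0) / np.maximum(n_inc, 1), 0.0)
    masked = np.ma.masked_array(beta, mask=~xi)
    med = np.ma.median(masked, axis=0).filled(0.0)
    return mean, med


@dataclass
class SelectionResult:
    """Selections and coefficient estimates derived from one chain."""

    ppi: np.ndarray
    threshold: float
    selected: np.ndarray
    fdr_estimate: float
    beta_cond_mean: np.ndarray
    beta_cond_median: np.ndarray
    beta_marg_mean: np.ndarray
    beta_marg_median: np.ndarray
    selected_median_model: np.ndarray
    fdr_attained: bool
    taxon_ids: list[str] | None = None
    covariate_ids: list[str] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format results table, one row per (covariate, taxon)."""
        P, J = self.ppi.shape
        covs = self.covariate_ids or [f"cov_{p}" for p in range(P)]
        taxa = self.taxon_ids or [f"taxon_{j}" for j in range(J)]
        p_idx, j_idx = np.meshgrid(np.arange(P), np.arange(J), indexing="ij")
        return pd.DataFrame(
            {
                "covariate_id": [covs[p] for p in p_idx.ravel()],
                "taxon_id": [taxa[j] for j in j_idx.ravel()],
                "ppi": self.ppi.ravel(),
                "beta_cond_mean": self.beta_cond_mean.ravel(),
                "beta_cond_median": self.beta_cond_median.ravel(),
                "selected_median_model": self.selected_median_model.ravel(),
                "selected_fdr": self.selected.ravel(),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def select(
    chain: PosteriorChain,
    burn_in: int | None = None,
    fdr_alpha: float = 0.1,
) -> SelectionResult:
    """Full selection pipeline: PPIs, both thresholds, beta summaries."""
    ppi = compute_ppi(chain, burn_in)
    c, attained = fdr_threshold(ppi, fdr_alpha)
    selected = (ppi > c).astype(np.uint8)
    cond_mean, cond_med = beta_summaries(chain, burn_in, conditional=True)
    marg_mean, marg_med = beta_summaries(chain, burn_in, conditional=False)
    return SelectionResult(
        ppi=ppi,
        threshold=c,
        selected=selected,
        fdr_estimate=bayesian_fdr(ppi, c),
        beta_cond_mean=cond_mean,
        beta_cond_median=cond_med,
        beta_marg_mean=marg_mean,
        beta_marg_median=marg_med,
        selected_median_model=median_model(ppi),
        fdr_attained=attained,
        taxon_ids=chain.taxon_ids,
        covariate_ids=chain.covariate_ids,
    )
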